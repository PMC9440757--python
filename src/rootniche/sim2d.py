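"""Pixel-grid 2D simulation of the mixed model on a root layout.

The reaction-diffusion system of the mixed model (BRAVO B, WOX5 W,
intermediary Z, plus one GFP reporter per promoter) is integrated on the
pixel lattice of a :class:`~rootniche.layout.RootLayout` with a
forward-time central-space (FTCS) scheme and heterogeneous diffusion:

* every species has one diffusion coefficient inside cells (``cyt``) and a
  smaller one on cell-wall pixels (``wall``); outside the root all
  coefficients are zero, which automatically makes the root border
  reflecting;
* BRAVO (and hence the implicit BRAVO-WOX5 complex) cannot cross walls
  (``D_B_wall = 0``);
* reactions (production, degradation, sequestration) run on cell pixels
  only — inside walls molecules only diffuse;
* WOX5 is produced in QC cells only; WOX5/Z activates BRAVO only in QC,
  VI, vascular, cortex and endodermis cells; basal BRAVO production is
  restricted to template-designated cells;
* GFP reporters share their promoter's production term, and all three
  reporters use one diffusion coefficient and one degradation rate.

The bravo mutant keeps B = 0 at all times while the BRAVO reporter keeps
evolving, so the promoter activity stays observable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np

from .layout import RootLayout
from .models import ConfigError, ModelParams, ModelSpec
from .solve1d import SolverError, StabilityError

__all__ = [
    "Params2D",
    "FieldMaps2D",
    "State2D",
    "build_field_maps",
    "heterogeneous_laplacian",
    "ftcs_run",
    "transverse_profile",
    "reduced_variant_run",
    "save_state_h5",
    "load_state_h5",
]

#: cell types in which the activator can drive BRAVO production
BRAVO_ACTIVATING_TYPES = ("QC", "VI", "V", "CX", "END")

SPECIES_2D = ("B", "W", "Z")
REPORTERS = ("B_GFP", "W_GFP", "Z_GFP")


@dataclass
class Params2D:
    """Transport parameters of the 2D model (length in pixels, so the
    diffusion coefficients are in px^2/time)."""

    D_cyt: Dict[str, float] = field(
        default_factory=lambda: {"B": 0.3, "W": 1.0, "Z": 1.0}
    )
    D_wall: Dict[str, float] = field(
        default_factory=lambda: {"B": 0.0, "W": 0.02, "Z": 0.15}
    )
    D_GFP_cyt: float = 0.5
    D_GFP_wall: float = 0.03
    d_GFP: float = 0.1
    face_average: str = "arithmetic"

    def __post_init__(self) -> None:
        if self.face_average not in ("arithmetic", "harmonic"):
            raise ConfigError("face_average must be 'arithmetic' or 'harmonic'")
        for s in SPECIES_2D:
            if s not in self.D_cyt or s not in self.D_wall:
                raise ConfigError(f"missing diffusion coefficients for species {s!r}")
            if self.D_cyt[s] < 0 or self.D_wall[s] < 0:
                raise ConfigError(f"negative diffusion coefficient for {s!r}")
            if self.D_wall[s] > self.D_cyt[s]:
                raise ConfigError(
                    f"wall diffusion must not exceed cytoplasmic diffusion ({s!r})"
                )
        if self.D_wall["B"] != 0.0:
            raise ConfigError("BRAVO cannot diffuse through cell walls (D_wall must be 0)")
        if self.D_GFP_wall > self.D_GFP_cyt or self.D_GFP_cyt < 0 or self.D_GFP_wall < 0:
            raise ConfigError("invalid GFP diffusion coefficients")
        if self.d_GFP <= 0:
            raise ConfigError("d_GFP must be positive")


@dataclass
class FieldMaps2D:
    """Per-pixel maps derived from a typed layout: diffusion per field,
    production masks, and the cell-only reaction mask."""

    layout: RootLayout
    Dmap: Dict[str, np.ndarray]
    cell_mask: np.ndarray
    gamma_mask: np.ndarray  # WOX5 production: QC pixels
    alpha_mask: np.ndarray  # activator-driven BRAVO production pixels
    basal_mask: np.ndarray  # basal BRAVO production pixels

    @property
    def shape(self) -> Tuple[int, int]:
        return self.layout.shape


def build_field_maps(
    layout: RootLayout, p2d: Optional[Params2D] = None
) -> FieldMaps2D:
    """Assemble diffusion and production maps from a typed layout."""
    p2d = p2d or Params2D()
    if not layout.cell_types:
        raise ConfigError("layout has no cell types; run assign_cell_types first")
    qc = layout.type_mask("QC")
    if not qc.any():
        raise ConfigError("layout has no QC cells")
    cell = layout.cell_mask
    wall = layout.wall_mask

    Dmap: Dict[str, np.ndarray] = {}
    for s in SPECIES_2D:
        m = np.zeros(layout.shape)
        m[cell] = p2d.D_cyt[s]
        m[wall] = p2d.D_wall[s]
        Dmap[s] = m
    gfp = np.zeros(layout.shape)
    gfp[cell] = p2d.D_GFP_cyt
    gfp[wall] = p2d.D_GFP_wall
    for r in REPORTERS:
        Dmap[r] = gfp

    alpha_mask = layout.type_mask(*BRAVO_ACTIVATING_TYPES)
    basal_mask = np.isin(layout.labels, sorted(layout.basal_cells))
    return FieldMaps2D(
        layout=layout,
        Dmap=Dmap,
        cell_mask=cell,
        gamma_mask=qc,
        alpha_mask=alpha_mask,
        basal_mask=basal_mask,
    )


@dataclass
class State2D:
    """Concentration fields over the lattice at time t."""

    fields: Dict[str, np.ndarray]
    t: float = 0.0
    meta: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.fields[name]

    @classmethod
    def zeros(cls, shape: Tuple[int, int]) -> "State2D":
        return cls(fields={n: np.zeros(shape) for n in SPECIES_2D + REPORTERS})


def _face_pair(a: np.ndarray, b: np.ndarray, mode: str) -> np.ndarray:
    if mode == "harmonic":
        s = a + b
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(s > 0, 2.0 * a * b / np.where(s > 0, s, 1.0), 0.0)
        return out
    out = 0.5 * (a + b)
    out[(a == 0) | (b == 0)] = 0.0
    return out


def _faces(Dmap: np.ndarray, mode: str = "arithmetic") -> Tuple[np.ndarray, np.ndarray]:
    """Face diffusivities between adjacent pixels: arithmetic mean by
    default (harmonic optional), zero whenever either side is zero (no
    flux into zero-D regions)."""
    fx = _face_pair(Dmap[:, :-1], Dmap[:, 1:], mode)
    fy = _face_pair(Dmap[:-1, :], Dmap[1:, :], mode)
    return fx, fy


def _div_flux(u: np.ndarray, fx: np.ndarray, fy: np.ndarray, dx: float, dy: float) -> np.ndarray:
    flux_x = fx * (u[:, 1:] - u[:, :-1]) / dx
    flux_y = fy * (u[1:, :] - u[:-1, :]) / dy
    out = np.zeros_like(u)
    out[:, :-1] += flux_x / dx
    out[:, 1:] -= flux_x / dx
    out[:-1, :] += flux_y / dy
    out[1:, :] -= flux_y / dy
    return out


def heterogeneous_laplacian(
    field: np.ndarray, Dmap: np.ndarray, dx: float = 1.0, dy: float = 1.0, face_average: str = "arithmetic"
) -> np.ndarray:
    """Conservative discretization of ``div(D grad u)`` on the pixel grid.

    Face diffusivities are the arithmetic mean of the two adjacent pixels
    and vanish when either pixel has zero diffusivity, which implements
    reflecting boundaries at the root border exactly (total mass is
    conserved to machine precision under pure diffusion).
    """
    if np.any(np.asarray(Dmap) < 0):
        raise ConfigError("negative entries in the diffusion map")
    if face_average not in ("arithmetic", "harmonic"):
        raise ConfigError("face_average must be 'arithmetic' or 'harmonic'")
    fx, fy = _faces(np.asarray(Dmap, float), face_average)
    return _div_flux(np.asarray(field, float), fx, fy, dx, dy)


def ftcs_run(
    maps: FieldMaps2D,
    p: ModelParams,
    spec: ModelSpec,
    p2d: Optional[Params2D] = None,
    state0: Optional[State2D] = None,
    dt: float = 0.1,
    t_end: float = 3000.0,
    dx: float = 1.0,
    dy: float = 1.0,
    check_every: int = 500,
) -> State2D:
    """Integrate the 2D mixed model to ``t_end`` with the FTCS scheme.

    The stability bound ``max(D)*dt*(1/dx^2 + 1/dy^2) <= 1/2`` is checked
    for every field before stepping.  The spec's ``genotype`` selects wild
    type or the bravo mutant (B held at zero, reporter kept).
    """
    p2d = p2d or Params2D()
    maxD = max(float(np.max(D)) for D in maps.Dmap.values())
    if maxD * dt * (1.0 / dx**2 + 1.0 / dy**2) > 0.5 + 1e-12:
        raise StabilityError(
            f"max(D)*dt*(1/dx^2+1/dy^2) = {maxD * dt * (1 / dx**2 + 1 / dy**2):.3g} > 1/2; "
            f"reduce dt below {0.5 / (maxD * (1 / dx**2 + 1 / dy**2)):.3g}"
        )
    if dt <= 0:
        raise ConfigError("dt must be positive")

    mutant = spec.genotype == "bravo"
    state = state0 or State2D.zeros(maps.shape)
    fields = {k: v.copy() for k, v in state.fields.items()}
    if mutant:
        fields["B"][:] = 0.0

    cell = maps.cell_mask
    faces = {name: _faces(maps.Dmap[name], p2d.face_average) for name in fields}
    gamma_arr = p.gamma * maps.gamma_mask
    basal_arr = p.alpha_0 * maps.basal_mask

    n_steps = int(round(t_end / dt))
    kn = p.k_Z**p.n
    kBn = p.k_B**p.n
    for k in range(n_steps):
        B, W, Z = fields["B"], fields["W"], fields["Z"]
        Zn = Z**p.n
        Wn = W**p.n
        P_B = (p.alpha * maps.alpha_mask) * (Zn / (kBn + Zn)) + basal_arr
        if spec.wox5_self_repression:
            P_W = gamma_arr / (1.0 + (W / p.k_W) ** p.h)
        else:
            P_W = gamma_arr
        P_Z = (p.beta * Wn / (kn + Wn)) * cell / (1.0 + p.c * B)

        seq = p.lam * B * W
        react = {
            "B": P_B - p.d_B * B - seq,
            "W": P_W - p.d_W * W - seq,
            "Z": P_Z - p.d_Z * Z,
            "B_GFP": P_B - p2d.d_GFP * fields["B_GFP"],
            "W_GFP": P_W - p2d.d_GFP * fields["W_GFP"],
            "Z_GFP": P_Z - p2d.d_GFP * fields["Z_GFP"],
        }
        for name, u in fields.items():
            if mutant and name == "B":
                continue
            fx, fy = faces[name]
            u += dt * (_div_flux(u, fx, fy, dx, dy) + np.where(cell, react[name], 0.0))
            np.maximum(u, 0.0, out=u)
        if (k + 1) % check_every == 0:
            for name, u in fields.items():
                if not np.all(np.isfinite(u)):
                    raise SolverError(f"non-finite value in field {name!r} at step {k + 1}")

    return State2D(
        fields=fields,
        t=n_steps * dt,
        meta={"dt": dt, "t_end": t_end, "genotype": spec.genotype},
    )


def transverse_profile(field: np.ndarray, layout: RootLayout) -> np.ndarray:
    """Sum of a field over the transverse direction (root pixels only),
    giving one value per row along the root axis."""
    field = np.asarray(field, float)
    if field.shape != layout.shape:
        raise ConfigError("field does not match the layout lattice")
    return np.where(layout.root_mask, field, 0.0).sum(axis=1)


def reduced_variant_run(
    maps: FieldMaps2D,
    p: ModelParams,
    spec: ModelSpec,
    overrides: Optional[Dict[str, float]] = None,
    p2d: Optional[Params2D] = None,
    **run_kw,
) -> Tuple[State2D, State2D]:
    """Run a wild-type/mutant pair with single-parameter overrides.

    Supported overrides: ``c`` (repression strength), ``lambda``
    (sequestration) and ``D_Z_wall`` / ``D_Z_cyt`` (Z mobility).  The
    mutant's BRAVO-reporter dynamics are unaffected by ``c`` and
    ``lambda`` overrides because both act only through B.
    """
    p2d = p2d or Params2D()
    overrides = overrides or {}
    for key, val in overrides.items():
        if key == "c":
            p = p.with_(c=float(val))
        elif key == "lambda":
            p = p.with_(lam=float(val))
        elif key == "D_Z_wall":
            p2d = replace(p2d, D_wall={**p2d.D_wall, "Z": float(val)})
        elif key == "D_Z_cyt":
            d = float(val)
            p2d = replace(
                p2d,
                D_cyt={**p2d.D_cyt, "Z": d},
                D_wall={**p2d.D_wall, "Z": min(d, p2d.D_wall["Z"])},
            )
        else:
            raise ConfigError(f"unsupported override {key!r}")
    maps = build_field_maps(maps.layout, p2d)
    wt = ftcs_run(maps, p, replace(spec, genotype="wt"), p2d=p2d, **run_kw)
    mut = ftcs_run(maps, p, replace(spec, genotype="bravo"), p2d=p2d, **run_kw)
    return wt, mut


def save_state_h5(path, state: State2D, layout: Optional[RootLayout] = None) -> None:
    """Write fields (one dataset per species) and metadata to HDF5."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["t"] = state.t
        for k, v in state.meta.items():
            fh.attrs[k] = v
        for name, u in state.fields.items():
            fh.create_dataset(name, data=u, compression="gzip")
        if layout is not None:
            fh.create_dataset("labels", data=layout.labels, compression="gzip")


def load_state_h5(path) -> State2D:
    import h5py

    with h5py.File(path, "r") as fh:
        fields = {k: np.asarray(fh[k]) for k in fh.keys() if k != "labels"}
        meta = dict(fh.attrs)
        t = float(meta.pop("t", 0.0))
    return State2D(fields=fields, t=t, meta=meta)
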