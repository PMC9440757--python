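"""Stationary 1D profiles by two independent routes.

The stationary state of each model variant is computed either by

* :func:`solve_stationary_bvp` — eliminate the non-diffusible species from
  their stationary relations, cast the remaining second-order system as a
  boundary value problem and solve it with ``scipy.integrate.solve_bvp``; or
* :func:`integrate_to_steady` — explicit forward-Euler time stepping of the
  full reaction-diffusion system with a central-difference Laplacian from
  zero initial conditions.

Both routes use zero Dirichlet boundaries for B, W and Z (the competing
sequestrator S is periodic).  Agreement of the two routes on the same
parameters is the package's standing cross-validation.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from typing import Dict, Optional

import numpy as np
from scipy.integrate import solve_bvp

from .models import (
    ConfigError,
    FullModelParams,
    Grid1D,
    ModelParams,
    ModelSpec,
    activator_species,
    full_complex_rhs,
    lambda_eff,
    model_rhs,
    prod_bravo,
    prod_wox5,
    prod_z,
    species_for,
)

__all__ = [
    "StationaryState1D",
    "PromoterProfiles",
    "SolverError",
    "StabilityError",
    "solve_stationary_bvp",
    "integrate_to_steady",
    "promoter_profiles",
    "write_profiles_csv",
    "params_hash",
]


class SolverError(RuntimeError):
    """Solver failed to converge to a stationary state."""


class StabilityError(ValueError):
    """Explicit time step violates the diffusive stability bound."""


#: diffusion coefficient lookup per species name
def _diffusion(p: ModelParams, s: str) -> float:
    return {"W": p.D_W, "Z": p.D_Z, "S": p.D_S}.get(s, 0.0)


@dataclass
class StationaryState1D:
    """Stationary concentration profiles on a 1D grid.

    ``conc`` maps species names ("B", "W", "Z", "S", "C") to arrays over
    grid nodes; species absent from the variant (or B in the bravo mutant)
    are omitted.  ``residual`` is the max-norm of the stationary
    reaction-diffusion residual evaluated on the grid.
    """

    grid: Grid1D
    spec: ModelSpec
    params: ModelParams
    conc: Dict[str, np.ndarray]
    method: str
    residual: float
    meta: dict = field(default_factory=dict)

    def __getitem__(self, s: str) -> np.ndarray:
        return self.conc[s]

    @property
    def B_s(self) -> Optional[np.ndarray]:
        return self.conc.get("B")

    @property
    def W_s(self) -> Optional[np.ndarray]:
        return self.conc.get("W")

    @property
    def Z_s(self) -> Optional[np.ndarray]:
        return self.conc.get("Z")


@dataclass
class PromoterProfiles:
    """Stationary promoter activities: the production functions evaluated on
    the stationary profiles (pW is zero outside the QC)."""

    x: np.ndarray
    pB: np.ndarray
    pW: np.ndarray
    pZ: Optional[np.ndarray] = None


def params_hash(p: ModelParams, spec: ModelSpec) -> str:
    """Short stable hash of a parameter set + model spec, for provenance."""
    payload = json.dumps({"params": asdict(p), "spec": asdict(spec)}, sort_keys=True)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# explicit Euler route
# ---------------------------------------------------------------------------

def integrate_to_steady(
    spec: ModelSpec,
    p: ModelParams,
    grid: Optional[Grid1D] = None,
    dt: float = 0.01,
    t_final: float = 1000.0,
    fp: Optional[FullModelParams] = None,
    check_every: int = 1000,
    rel_change_tol: float = 1e-6,
) -> StationaryState1D:
    """Forward-Euler integration to ``t_final`` from zero initial conditions.

    The Laplacian is the standard central difference
    ``(u(x+dx) - 2 u(x) + u(x-dx))/dx^2``; boundary nodes are held at zero
    (S: periodic).  The diffusive stability bound ``dt*D/dx^2 <= 1/2`` is
    enforced before stepping.  Convergence is assessed from the relative
    change of the state over the last 1% of the integration and recorded in
    ``meta``; a warning is emitted if it exceeds ``rel_change_tol``.
    """
    grid = grid or Grid1D.euler_default()
    if dt <= 0:
        raise ConfigError("dt must be positive")
    species = species_for(spec)
    dx2 = grid.dx**2
    for s in species:
        D = _diffusion(p, s)
        if dt * D / dx2 > 0.5 + 1e-12:
            raise StabilityError(
                f"dt*D/dx^2 = {dt * D / dx2:.3g} > 1/2 for species {s!r}; "
                f"reduce dt below {0.5 * dx2 / D:.3g}"
            )

    x = grid.x
    state = {s: np.zeros_like(x) for s in species}
    n_steps = int(round(t_final / dt))
    snap_step = max(1, n_steps - max(1, n_steps // 100))
    snapshot: Dict[str, np.ndarray] = {}

    if spec.variant == "full_complex":
        fp = fp or FullModelParams()
        reaction = lambda st: full_complex_rhs(st, x, p, fp, spec)
    else:
        reaction = lambda st: model_rhs(st, x, p, spec)

    for k in range(n_steps):
        deriv = reaction(state)
        for s in species:
            u = state[s]
            du = deriv[s]
            D = _diffusion(p, s)
            if D > 0:
                if s == "S":
                    lap = (np.roll(u, 1) - 2 * u + np.roll(u, -1)) / dx2
                    u += dt * (du + D * lap)
                else:
                    u[1:-1] += dt * (du[1:-1] + D * (u[:-2] - 2 * u[1:-1] + u[2:]) / dx2)
            else:
                u += dt * du
                if s != "S":
                    u[0] = 0.0
                    u[-1] = 0.0
            # explicit overshoot guard; at stable steps this only clips
            # roundoff-level negatives
            np.maximum(u, 0.0, out=u)
        if (k + 1) % check_every == 0:
            for s in species:
                if not np.all(np.isfinite(state[s])):
                    raise SolverError(f"non-finite value in {s!r} at step {k + 1}")
        if k + 1 == snap_step:
            snapshot = {s: state[s].copy() for s in species}

    rel_change = 0.0
    for s in species:
        scale = max(np.max(np.abs(state[s])), 1e-300)
        if snapshot:
            rel_change = max(rel_change, float(np.max(np.abs(state[s] - snapshot[s])) / scale))
    if rel_change > rel_change_tol:
        warnings.warn(
            f"Euler integration not stationary: relative change {rel_change:.2e} over "
            f"the last 1% of steps exceeds {rel_change_tol:.0e}; increase t_final",
            RuntimeWarning,
            stacklevel=2,
        )

    residual = _full_residual(state, x, grid.dx, p, spec, fp)
    return StationaryState1D(
        grid=grid,
        spec=spec,
        params=p,
        conc=state,
        method="euler",
        residual=residual,
        meta={"dt": dt, "t_final": t_final, "rel_change_last_1pct": rel_change},
    )


def _full_residual(state, x, dx, p, spec, fp=None, w: float = 0.0) -> float:
    """Max-norm of reaction + diffusion at interior nodes."""
    if spec.variant == "full_complex":
        deriv = full_complex_rhs(state, x, p, fp or FullModelParams(), spec, w)
    else:
        deriv = model_rhs(state, x, p, spec, w)
    res = 0.0
    for s, du in deriv.items():
        u = state[s]
        D = _diffusion(p, s)
        total = du.copy()
        if D > 0:
            if s == "S":
                total += D * (np.roll(u, 1) - 2 * u + np.roll(u, -1)) / dx**2
                res = max(res, float(np.max(np.abs(total))))
                continue
            total[1:-1] += D * (u[:-2] - 2 * u[1:-1] + u[2:]) / dx**2
        res = max(res, float(np.max(np.abs(total[1:-1]))))
    return res


# ---------------------------------------------------------------------------
# boundary-value route
# ---------------------------------------------------------------------------

def _eliminate(
    diff_state: Dict[str, np.ndarray],
    x: np.ndarray,
    p: ModelParams,
    spec: ModelSpec,
    fp: Optional[FullModelParams],
    w: float = 0.0,
) -> Dict[str, np.ndarray]:
    """Solve the stationary relations of the non-diffusible species given the
    diffusible ones, returning the full state."""
    state = {s: np.maximum(v, 0.0) for s, v in diff_state.items()}
    lam = lambda_eff(fp) if spec.variant == "full_complex" else (p.lam if spec.sequestering else 0.0)

    if "W" not in state:  # W non-diffusible (repression variant with D_W = 0)
        if spec.sequestering or spec.variant == "full_complex":
            raise ConfigError(
                "stationary elimination of a non-diffusible W is only supported "
                "without sequestration; use the Euler route instead"
            )
        state["W"] = _stationary_w_nodiff(x, p, spec, w)
    W = state["W"]
    mutant = spec.genotype == "bravo"

    if spec.variant == "sequestration_S" and "S" not in state:
        if p.d_S <= 0:
            raise ConfigError("d_S must be positive to eliminate a non-diffusible S")
        state["S"] = p.alpha_S / (p.d_S + p.lambda_S * W)

    if spec.z_activated and "Z" not in state:
        # non-diffusible intermediary: Z = P_Z(W, B)/d_Z.  Without repression
        # (or in the mutant, B = 0) this is explicit; with repression, B and Z
        # determine each other and a fixed-point iteration converges since
        # both maps are monotone and bounded.
        if p.d_Z <= 0:
            raise ConfigError("d_Z must be positive to eliminate a non-diffusible Z")
        if mutant or not spec.repressing:
            state["Z"] = prod_z(W, np.zeros_like(W), p, spec) / p.d_Z
        else:
            Z = prod_z(W, np.zeros_like(W), p, spec) / p.d_Z
            for _ in range(200):
                B = prod_bravo(Z, x, p, spec, w) / (p.d_B + lam * W)
                Z_new = prod_z(W, B, p, spec) / p.d_Z
                delta = float(np.max(np.abs(Z_new - Z)))
                Z = Z_new
                if delta < 1e-13 * max(1.0, float(np.max(Z))):
                    break
            state["Z"] = Z

    if mutant:
        if spec.variant == "full_complex":
            state["C"] = np.zeros_like(W)
        return state
    act = state[activator_species(spec)]
    B = prod_bravo(act, x, p, spec, w) / (p.d_B + lam * W)
    state["B"] = B
    if spec.variant == "full_complex":
        denom = fp.k_off + fp.d_C
        if denom == 0.0:
            if fp.k_on > 0:
                raise ConfigError(
                    "k_off = d_C = 0: the explicit complex accumulates without bound "
                    "and has no stationary state"
                )
            state["C"] = np.zeros_like(W)
        else:
            state["C"] = fp.k_on * B * W / denom
    return state


def _stationary_w_nodiff(x: np.ndarray, p: ModelParams, spec: ModelSpec, w: float = 0.0) -> np.ndarray:
    """Stationary W when D_W = 0 and no sequestration: P_W(W, x) = d_W * W."""
    if p.d_W <= 0:
        raise ConfigError("d_W must be positive to solve for a stationary W")
    from .models import qc_indicator

    g = p.gamma * np.asarray(qc_indicator(x, p.L_QC, w))
    if not spec.wox5_self_repression:
        return g / p.d_W
    if p.h == 1:
        # d_W*W*(1 + W/k_W) = g  ->  positive root of the quadratic
        return 0.5 * p.k_W * (-1.0 + np.sqrt(1.0 + 4.0 * g / (p.d_W * p.k_W)))
    W = g / p.d_W  # Newton from the unrepressed value
    for _ in range(100):
        f = g / (1.0 + (W / p.k_W) ** p.h) - p.d_W * W
        fp_ = -g * p.h * (W / p.k_W) ** (p.h - 1) / p.k_W / (1.0 + (W / p.k_W) ** p.h) ** 2 - p.d_W
        step = f / fp_
        W = np.maximum(W - step, 0.0)
        if np.max(np.abs(step)) < 1e-14 * max(1.0, float(np.max(W))):
            break
    return W


def solve_stationary_bvp(
    spec: ModelSpec,
    p: ModelParams,
    grid: Optional[Grid1D] = None,
    fp: Optional[FullModelParams] = None,
    tol: float = 1e-8,
    max_nodes: int = 200_000,
    warmup_t: float = 300.0,
    mask_width: Optional[float] = None,
) -> StationaryState1D:
    """Stationary profiles via boundary-value reduction.

    Non-diffusible species are eliminated from their stationary relations
    (e.g. for sequestration ``B = P_B/(d_B + lambda*W)``) and the remaining
    second-order system is solved with zero Dirichlet boundaries (S:
    periodic).  The initial guess comes from a short coarse Euler
    integration; the mesh is refined internally by ``solve_bvp`` and the
    result is reported on the user grid.
    """
    grid = grid or Grid1D.bvp_default()
    w = grid.dx if mask_width is None else mask_width
    if spec.variant == "full_complex":
        fp = fp or FullModelParams()
    species = species_for(spec)
    diff_species = [s for s in species if _diffusion(p, s) > 0]
    if not diff_species:
        raise ConfigError(
            "no diffusible species: the stationary problem is purely local; "
            "use a reaction fixed-point computation instead of the BVP route"
        )

    # --- warm start from a coarse, short Euler run on the same domain
    span = grid.x_max - grid.x_min
    coarse_dx = max(grid.dx, span / 600.0)
    n = int(round(span / coarse_dx))
    coarse = Grid1D(grid.x_min, grid.x_max, span / n)
    maxD = max(_diffusion(p, s) for s in diff_species)
    dt = 0.4 * coarse.dx**2 / maxD
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        warm = integrate_to_steady(spec, p, coarse, dt=dt, t_final=warmup_t, fp=fp)

    # the initial mesh is the user grid itself: its nodes coincide with the
    # discontinuities of the step-function sources (at +-L_QC/2 and the VI
    # end), so every collocation interval sees a smooth right-hand side
    x_init = grid.x
    m = len(diff_species)
    y_init = np.zeros((2 * m, x_init.size))
    for i, s in enumerate(diff_species):
        u = np.interp(x_init, coarse.x, warm.conc[s])
        y_init[2 * i] = u
        y_init[2 * i + 1] = np.gradient(u, x_init)

    lam_full = lambda_eff(fp) if spec.variant == "full_complex" else None

    def fun(xv, y):
        diff_state = {s: y[2 * i] for i, s in enumerate(diff_species)}
        full = _eliminate(diff_state, xv, p, spec, fp, w)
        dy = np.empty_like(y)
        W = full["W"]
        B = full.get("B", np.zeros_like(W))
        for i, s in enumerate(diff_species):
            D = _diffusion(p, s)
            if s == "W":
                lam = lam_full if lam_full is not None else (p.lam if spec.sequestering else 0.0)
                reac = prod_wox5(W, xv, p, spec, w) - p.d_W * W - lam * B * W
                if spec.variant == "sequestration_S":
                    reac = reac - p.lambda_S * full["S"] * W
            elif s == "Z":
                reac = prod_z(W, B, p, spec) - p.d_Z * full["Z"]
            elif s == "S":
                reac = p.alpha_S - p.d_S * full["S"] - p.lambda_S * full["S"] * W
            else:  # pragma: no cover - diffusible set is W/Z/S by construction
                raise ConfigError(f"unexpected diffusible species {s!r}")
            dy[2 * i] = y[2 * i + 1]
            dy[2 * i + 1] = -reac / D
        return dy

    def bc(ya, yb):
        out = np.empty(2 * m)
        for i, s in enumerate(diff_species):
            if s == "S":  # periodic value and slope
                out[2 * i] = ya[2 * i] - yb[2 * i]
                out[2 * i + 1] = ya[2 * i + 1] - yb[2 * i + 1]
            else:  # zero Dirichlet at both ends
                out[2 * i] = ya[2 * i]
                out[2 * i + 1] = yb[2 * i]
        return out

    sol = solve_bvp(fun, bc, x_init, y_init, tol=tol, max_nodes=max_nodes)
    if sol.status != 0:
        raise SolverError(
            f"solve_bvp failed (status {sol.status}: {sol.message}); "
            f"max rms residual {np.max(sol.rms_residuals):.2e}"
        )

    x = grid.x
    yx = sol.sol(x)
    # report with the sharp step masks: the smoothing is a collocation aid,
    # not part of the model, and eliminated species follow the printed forms
    diff_state = {s: np.maximum(yx[2 * i], 0.0) for i, s in enumerate(diff_species)}
    conc = _eliminate(diff_state, x, p, spec, fp)
    conc = {s: conc[s] for s in species}  # variant ordering; drop helpers

    residual = _full_residual(conc, x, grid.dx, p, spec, fp)
    return StationaryState1D(
        grid=grid,
        spec=spec,
        params=p,
        conc=conc,
        method="bvp",
        residual=residual,
        meta={
            "bvp_rms_residual": float(np.max(sol.rms_residuals)),
            "bvp_nodes": int(sol.x.size),
            "tol": tol,
            "mask_width": w,
        },
    )


# ---------------------------------------------------------------------------
# promoter activities
# ---------------------------------------------------------------------------

def promoter_profiles(state: StationaryState1D, spec: Optional[ModelSpec] = None, p: Optional[ModelParams] = None) -> PromoterProfiles:
    """Promoter activities evaluated on the stationary profiles.

    ``pB = P_B(activator_s, x)``, ``pW = P_W(W_s, x)``, and for variants
    with Z, ``pZ = P_Z(W_s, B_s)``.  In the bravo mutant, pB is computed
    from the mutant's own activator profile (the promoter is intact even
    though the protein is absent) and pZ uses B = 0.
    """
    spec = spec or state.spec
    p = p or state.params
    x = state.grid.x
    act = state.conc[activator_species(spec)]
    W = state.conc["W"]
    B = state.conc.get("B", np.zeros_like(x))
    pB = np.asarray(prod_bravo(act, x, p, spec), dtype=float)
    pW = np.asarray(prod_wox5(W, x, p, spec), dtype=float) * np.ones_like(x)
    pZ = None
    if "Z" in state.conc:
        pZ = np.asarray(prod_z(W, B, p, spec), dtype=float) * np.ones_like(x)
    return PromoterProfiles(x=x, pB=pB, pW=pW, pZ=pZ)


def write_profiles_csv(path, state: StationaryState1D, profiles: Optional[PromoterProfiles] = None) -> None:
    """Write stationary profiles (and promoter activities) as CSV with
    provenance header lines."""
    import pandas as pd

    profiles = profiles or promoter_profiles(state)
    cols = {"x": state.grid.x}
    for s in ("B", "W", "Z", "S", "C"):
        if s in state.conc:
            cols[s] = state.conc[s]
    cols["pB"] = profiles.pB
    cols["pW"] = profiles.pW
    if profiles.pZ is not None:
        cols["pZ"] = profiles.pZ
    df = pd.DataFrame(cols)
    header = (
        f"#variant={state.spec.variant}\n"
        f"#genotype={state.spec.genotype}\n"
        f"#method={state.method}\n"
        f"#params-hash={params_hash(state.params, state.spec)}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)
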