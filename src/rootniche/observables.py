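"""Compatibility observables and parameter-plane scans.

Four dimensionless observables compare a wild-type/mutant pair of
stationary solutions with experimental observations:

``xi = delta_x / L_QC``
    Spatial expansion of the mutant BRAVO promoter profile beyond the
    wild-type reference level ``pB* = pB_wt(x_VI)`` at the end of the VI,
    in units of the QC length.
``R_B = pB_mut(0) / pB_wt(0)``
    Fold increase of BRAVO promoter activity at the QC center in the
    mutant.
``R_BW = pB_wt(x_VI) / pW_wt(0)``
    Wild-type BRAVO promoter activity at the end of the VI relative to
    WOX5 promoter activity at the QC center.
``R_W = pW_mut(0) / pW_wt(0)``
    Mutant/wild-type ratio of WOX5 promoter activity at the QC; meaningful
    only when BRAVO feeds back on the WOX5 promoter (sequestration with
    WOX5 self-repression).

A parameter pair is "compatible" when every applicable observable falls in
its experimental range (xi in [0.5, 5], R_B in [1, 2], R_BW in [0.05, 0.5],
R_W in [0.5, 0.9], endpoints inclusive).  Scans evaluate the observables on
a log-spaced rectangular lattice (15 x 15 by default) of parameter pairs
using the explicit Euler route.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields as dc_fields
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import ConfigError, Grid1D, ModelParams, ModelSpec
from .solve1d import (
    PromoterProfiles,
    StationaryState1D,
    integrate_to_steady,
    promoter_profiles,
    solve_stationary_bvp,
)

__all__ = [
    "ObservableSet",
    "CompatibilityRanges",
    "ScanResult",
    "compute_delta_x",
    "compute_observables",
    "solve_pair",
    "scan_plane",
    "robustness_to_wox5",
    "efold_length",
]


@dataclass
class ObservableSet:
    """Observables for one wild-type/mutant pair.

    ``delta_x`` may be negative when the mutant profile lies below the
    wild-type reference; when the mutant profile never reaches the
    reference level, ``delta_x`` carries the sentinel ``-(x_VI - x_min)``
    and ``no_crossing`` is set.
    """

    delta_x: float
    xi: float
    R_B: float
    R_BW: float
    R_W: Optional[float]
    pB_star: float
    no_crossing: bool = False
    multiple_crossings: bool = False


@dataclass
class CompatibilityRanges:
    """Inclusive observable ranges considered compatible with experiments."""

    xi_range: Tuple[float, float] = (0.5, 5.0)
    R_B_range: Tuple[float, float] = (1.0, 2.0)
    R_BW_range: Tuple[float, float] = (0.05, 0.5)
    R_W_range: Tuple[float, float] = (0.5, 0.9)

    def check(self, obs: ObservableSet) -> Tuple[bool, str]:
        """AND of all applicable range tests; R_W is skipped when the model
        does not couple BRAVO to the WOX5 promoter (obs.R_W is None)."""
        tests = [("xi", obs.xi, self.xi_range), ("R_B", obs.R_B, self.R_B_range),
                 ("R_BW", obs.R_BW, self.R_BW_range)]
        if obs.R_W is not None:
            tests.append(("R_W", obs.R_W, self.R_W_range))
        bad = [name for name, v, (lo, hi) in tests if not (lo <= v <= hi)]
        return (not bad, "" if not bad else "out of range: " + ",".join(bad))


def compute_delta_x(
    pB_wt: np.ndarray, pB_mut: np.ndarray, grid: Grid1D, x_vi: float
) -> Tuple[float, float, bool, bool]:
    """Expansion of the mutant BRAVO promoter profile past the wild-type level.

    ``pB* = pB_wt(x_VI)``; ``x^bravo`` is the largest x at which the mutant
    profile crosses pB*, located by linear interpolation on the decaying
    shootward tail; ``delta_x = x^bravo - x_VI``.

    Returns ``(delta_x, pB_star, no_crossing, multiple_crossings)``.
    """
    x = grid.x
    pB_wt = np.asarray(pB_wt, float)
    pB_mut = np.asarray(pB_mut, float)
    if pB_wt.shape != x.shape or pB_mut.shape != x.shape:
        raise ConfigError("profiles must live on the given grid")
    pB_star = float(np.interp(x_vi, x, pB_wt))
    if pB_star <= 0:
        raise ConfigError("pB_wt(x_VI) must be positive to define the expansion")

    d = pB_mut - pB_star
    if np.max(pB_mut) < pB_star:
        warnings.warn(
            "mutant pB profile never reaches the wild-type reference level; "
            "reporting the no-crossing sentinel",
            RuntimeWarning,
            stacklevel=2,
        )
        return -(x_vi - grid.x_min), pB_star, True, False

    # restrict crossing detection to the decaying tail (after the profile max)
    imax = int(np.argmax(pB_mut))
    tail = d[imax:]
    sign = tail >= 0
    idx = np.nonzero(sign[:-1] & ~sign[1:])[0]
    if idx.size == 0:
        # profile max touches pB_star exactly but never dips below on the
        # tail (flat boundary case); use the last node at/above the level
        j = imax + int(np.nonzero(sign)[0][-1])
        return float(x[j] - x_vi), pB_star, False, False
    multi = idx.size > 1
    if multi:
        warnings.warn(
            "non-monotone mutant pB tail crosses the reference level more "
            "than once; using the rightmost crossing",
            RuntimeWarning,
            stacklevel=2,
        )
    i = imax + int(idx[-1])
    # linear interpolation inside [x_i, x_i+1]
    x_cross = x[i] + (x[i + 1] - x[i]) * d[i] / (d[i] - d[i + 1])
    return float(x_cross - x_vi), pB_star, False, multi


def compute_observables(
    wt: Tuple[StationaryState1D, PromoterProfiles],
    mut: Tuple[StationaryState1D, PromoterProfiles],
    p: Optional[ModelParams] = None,
    spec: Optional[ModelSpec] = None,
) -> ObservableSet:
    """Observables from matched wild-type and mutant stationary solutions."""
    wt_state, wt_prof = wt
    mut_state, mut_prof = mut
    p = p or wt_state.params
    spec = spec or wt_state.spec
    grid = wt_state.grid
    if mut_state.grid.n_nodes != grid.n_nodes or mut_state.grid.x_min != grid.x_min:
        raise ConfigError("wild-type and mutant solutions must share a grid")
    x = grid.x
    x_vi = p.x_vi

    pB_wt0 = float(np.interp(0.0, x, wt_prof.pB))
    pW_wt0 = float(np.interp(0.0, x, wt_prof.pW))
    if pB_wt0 <= 0 or pW_wt0 <= 0:
        deg = "gamma" if pW_wt0 <= 0 else "alpha_L/alpha"
        raise ConfigError(f"zero promoter activity at the QC center (degenerate parameter: {deg})")

    delta_x, pB_star, no_cross, multi = compute_delta_x(wt_prof.pB, mut_prof.pB, grid, x_vi)
    R_B = float(np.interp(0.0, x, mut_prof.pB)) / pB_wt0
    R_BW = pB_star / pW_wt0
    R_W: Optional[float] = None
    if spec.wox5_self_repression and spec.sequestering and p.lam > 0:
        R_W = float(np.interp(0.0, x, mut_prof.pW)) / pW_wt0
    return ObservableSet(
        delta_x=delta_x,
        xi=delta_x / p.L_QC,
        R_B=R_B,
        R_BW=R_BW,
        R_W=R_W,
        pB_star=pB_star,
        no_crossing=no_cross,
        multiple_crossings=multi,
    )


def solve_pair(
    spec: ModelSpec,
    p: ModelParams,
    grid: Optional[Grid1D] = None,
    method: str = "euler",
    **solver_kw,
) -> Tuple[Tuple[StationaryState1D, PromoterProfiles], Tuple[StationaryState1D, PromoterProfiles]]:
    """Solve wild type and bravo mutant to stationarity and attach promoter
    profiles.  ``method`` is "euler" (scan route) or "bvp"."""
    from dataclasses import replace

    out = []
    for genotype in ("wt", "bravo"):
        sp = replace(spec, genotype=genotype)
        if method == "euler":
            st = integrate_to_steady(sp, p, grid, **solver_kw)
        elif method == "bvp":
            st = solve_stationary_bvp(sp, p, grid, **solver_kw)
        else:
            raise ConfigError(f"unknown method {method!r}")
        out.append((st, promoter_profiles(st)))
    return out[0], out[1]


@dataclass
class ScanResult:
    """Observables and compatibility on a log-spaced parameter lattice."""

    axis1: str
    axis2: str
    values1: np.ndarray
    values2: np.ndarray
    observables: List[List[Optional[ObservableSet]]]
    compatible: np.ndarray  # bool (n1, n2)
    reason: np.ndarray  # str (n1, n2)
    ranges: CompatibilityRanges = field(default_factory=CompatibilityRanges)

    @property
    def n_cells(self) -> int:
        return int(self.values1.size * self.values2.size)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, v1 in enumerate(self.values1):
            for j, v2 in enumerate(self.values2):
                obs = self.observables[i][j]
                rows.append(
                    {
                        self.axis1: v1,
                        self.axis2: v2,
                        "xi": obs.xi if obs else np.nan,
                        "R_B": obs.R_B if obs else np.nan,
                        "R_BW": obs.R_BW if obs else np.nan,
                        "R_W": (obs.R_W if obs and obs.R_W is not None else np.nan),
                        "compatible": bool(self.compatible[i, j]),
                        "reason": self.reason[i, j],
                    }
                )
        return pd.DataFrame(rows)

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def scan_plane(
    spec: ModelSpec,
    p_base: ModelParams,
    axis1: Tuple[str, float, float],
    axis2: Tuple[str, float, float],
    n_points: int = 15,
    grid: Optional[Grid1D] = None,
    ranges: Optional[CompatibilityRanges] = None,
    **solver_kw,
) -> ScanResult:
    """Evaluate the observables on an ``n_points x n_points`` log lattice.

    Each axis is ``(param_name, lo, hi)`` with ``lo > 0``.  Every cell
    solves wild type and mutant via the Euler route and tests
    compatibility; solver failures mark the cell incompatible with a
    reason and the scan continues.
    """
    ranges = ranges or CompatibilityRanges()
    valid = {f.name for f in dc_fields(ModelParams)}
    axis1 = ("lam" if axis1[0] == "lambda" else axis1[0], axis1[1], axis1[2])
    axis2 = ("lam" if axis2[0] == "lambda" else axis2[0], axis2[1], axis2[2])
    for name, lo, hi in (axis1, axis2):
        if name not in valid:
            raise ConfigError(f"unknown parameter axis {name!r}")
        if lo <= 0 or hi <= lo:
            raise ConfigError(f"axis {name!r} needs 0 < lo < hi for log spacing")
    v1 = np.logspace(np.log10(axis1[1]), np.log10(axis1[2]), n_points)
    v2 = np.logspace(np.log10(axis2[1]), np.log10(axis2[2]), n_points)

    observables: List[List[Optional[ObservableSet]]] = [[None] * n_points for _ in range(n_points)]
    compatible = np.zeros((n_points, n_points), dtype=bool)
    reason = np.full((n_points, n_points), "", dtype=object)
    grid_eff = grid or Grid1D.euler_default()
    for i, a in enumerate(v1):
        for j, b in enumerate(v2):
            p = p_base.with_(**{axis1[0]: float(a), axis2[0]: float(b)})
            # cap the explicit step at the cell's own stability bound so a
            # diffusion-coefficient axis can span decades in one scan
            kw = dict(solver_kw)
            maxD = max(p.D_W, p.D_Z, p.D_S if spec.variant == "sequestration_S" else 0.0)
            if maxD > 0:
                kw["dt"] = min(kw.get("dt", 0.01), 0.45 * grid_eff.dx**2 / maxD)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    wt, mut = solve_pair(spec, p, grid, method="euler", **kw)
                    obs = compute_observables(wt, mut, p, spec)
            except Exception as exc:  # per-cell failure: record, continue
                reason[i, j] = f"solver failure: {exc}"
                continue
            observables[i][j] = obs
            ok, why = ranges.check(obs)
            compatible[i, j] = ok
            reason[i, j] = why
    return ScanResult(
        axis1=axis1[0],
        axis2=axis2[0],
        values1=v1,
        values2=v2,
        observables=observables,
        compatible=compatible,
        reason=np.asarray(reason, dtype=object),
        ranges=ranges,
    )


def efold_length(x: np.ndarray, u: np.ndarray, x_lo: float, x_hi: float) -> float:
    """e-folding length of a decaying profile from a log-linear fit on
    ``[x_lo, x_hi]`` (positive result; direction given by the window)."""
    m = (x >= min(x_lo, x_hi)) & (x <= max(x_lo, x_hi)) & (u > 0)
    if m.sum() < 3:
        raise ConfigError("window contains fewer than 3 positive samples")
    slope = np.polyfit(x[m], np.log(u[m]), 1)[0]
    if slope == 0:
        return np.inf
    return float(1.0 / abs(slope))


def robustness_to_wox5(
    spec: ModelSpec,
    p: ModelParams,
    gamma_factors: Sequence[float],
    grid: Optional[Grid1D] = None,
    method: str = "euler",
    **solver_kw,
) -> pd.DataFrame:
    """Response of the wild-type BRAVO promoter profile to WOX5 production
    changes.

    Reruns the wild-type stationary solve with gamma scaled by each factor
    and reports pB(0), its fold-change relative to factor 1, and the
    shootward decay length of pB.
    """
    from dataclasses import replace

    spec = replace(spec, genotype="wt")
    rows = []
    ref_pB0: Optional[float] = None
    for f in gamma_factors:
        pf = p.with_(gamma=p.gamma * float(f))
        if method == "euler":
            st = integrate_to_steady(spec, pf, grid, **solver_kw)
        else:
            st = solve_stationary_bvp(spec, pf, grid, **solver_kw)
        prof = promoter_profiles(st)
        x = st.grid.x
        pB0 = float(np.interp(0.0, x, prof.pB))
        ell = efold_length(x, prof.pB, pf.x_vi, pf.x_vi + 4 * pf.L_QC)
        rows.append({"gamma_factor": float(f), "pB0": pB0, "decay_length": ell})
        if f == 1:
            ref_pB0 = pB0
    df = pd.DataFrame(rows)
    if ref_pB0 is None:
        ref_pB0 = float(np.interp(1.0, df["gamma_factor"], df["pB0"]))
    df["pB0_fold_change"] = df["pB0"] / ref_pB0
    return df
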