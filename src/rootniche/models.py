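"""Model definitions for the BRAVO/WOX5 self-confinement circuit.

The stem-cell niche of the Arabidopsis primary root hosts two transcription
factors: WOX5, produced in the quiescent center (QC) and mobile, and BRAVO,
immobile and expressed in the QC and the vascular initials (VI).  BRAVO
confines its own expression domain by attenuating its diffusible activator,
either by sequestering WOX5 into an immobile, inactive complex (bilinear loss
``lambda*B*W``) or by repressing the production of an intermediary activator
Z, or both.

This module holds the parameter containers, the model-variant switchboard,
the regulatory (production) functions and the reaction parts of the
right-hand sides for all one-dimensional model variants:

``sequestration``
    BRAVO activated directly by WOX5; BRAVO-WOX5 sequestration.
``sequestration_z``
    WOX5 activates a diffusible intermediary Z which activates BRAVO;
    sequestration retained.
``repression``
    BRAVO represses the production of Z; no sequestration.
``mixed``
    Both sequestration and repression.
``sequestration_S``
    Sequestration plus a competing sequestrator S that also binds WOX5.
``full_complex``
    Sequestration with the BRAVO-WOX5 complex modeled explicitly through
    mass-action binding/unbinding/degradation; its stationary states match
    the minimal sequestration model with the effective rate
    ``lambda_eff = k_on*d_C/(k_off + d_C)``.

Transport (diffusion) is handled by the solvers; the functions here return
reaction terms only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Dict, Tuple

import numpy as np

__all__ = [
    "ConfigError",
    "DomainError",
    "ModelParams",
    "FullModelParams",
    "ModelSpec",
    "Grid1D",
    "VARIANTS",
    "qc_indicator",
    "activation_mask",
    "vi_indicator",
    "prod_bravo",
    "prod_wox5",
    "prod_z",
    "model_rhs",
    "full_complex_rhs",
    "lambda_eff",
    "species_for",
    "activator_species",
]


class ConfigError(ValueError):
    """Inconsistent or invalid model configuration."""


class DomainError(ValueError):
    """Input outside the physical domain (e.g. negative concentration)."""


VARIANTS = (
    "sequestration",
    "sequestration_z",
    "repression",
    "mixed",
    "sequestration_S",
    "full_complex",
)

#: species integrated by each variant (the bravo mutant drops "B")
_VARIANT_SPECIES: Dict[str, Tuple[str, ...]] = {
    "sequestration": ("B", "W"),
    "sequestration_z": ("B", "W", "Z"),
    "repression": ("B", "W", "Z"),
    "mixed": ("B", "W", "Z"),
    "sequestration_S": ("B", "W", "S"),
    "full_complex": ("B", "W", "C"),
}

#: variants in which BRAVO production is driven by Z rather than directly by W
_Z_ACTIVATED = ("sequestration_z", "repression", "mixed")

#: variants carrying the bilinear BRAVO-WOX5 sequestration loss
_SEQUESTERING = ("sequestration", "sequestration_z", "mixed", "sequestration_S")

#: variants in which BRAVO represses Z production
_REPRESSING = ("repression", "mixed")


@dataclass
class ModelParams:
    """Kinetic, regulatory and transport constants for all model variants.

    Rates are in 1/time or concentration/time, diffusion coefficients in
    length^2/time, lengths in the arbitrary spatial units of the 1D models
    (the QC is ``L_QC = 15`` of these units).  Unused parameters of a given
    variant are ignored, never combined.

    Attributes
    ----------
    alpha_L : float
        Linear BRAVO production rate per unit activator concentration.
    alpha : float
        Saturated BRAVO production rate (Hill mode).
    k_B : float
        Activator concentration giving half-saturated BRAVO production.
    n : float
        Hill cooperativity of the activations (>= 1).
    gamma : float
        WOX5 production rate inside the QC.
    k_W : float
        WOX5 concentration at which self-repressed production is gamma/2.
    h : float
        WOX5 self-repression exponent (>= 1).
    beta_L, beta, k_Z : float
        Linear rate, saturated rate and half-saturation of Z activation
        by WOX5.
    c : float
        Repression strength of BRAVO on Z production; ``c = 0`` disables
        repression exactly.
    alpha_0 : float
        Basal (WOX5-independent) BRAVO production in the VI region.
    d_B, d_W, d_Z : float
        Linear degradation rates.
    lam : float
        Effective BRAVO-WOX5 sequestration rate per unit of each
        concentration (config key ``lambda``).
    D_W, D_Z : float
        Diffusion coefficients of WOX5 and Z.
    L_QC : float
        QC length; the VI occupies ``(L_QC/2, 3*L_QC/2]``.
    alpha_S, d_S, lambda_S, D_S : float
        Production, degradation, WOX5-binding rate and diffusion of the
        supplementary competing sequestrator S.
    """

    alpha_L: float = 0.2
    alpha: float = 1.0
    k_B: float = 1.0
    n: float = 2.0
    gamma: float = 1.0
    k_W: float = 1.0
    h: float = 1.0
    beta_L: float = 0.1
    beta: float = 1.0
    k_Z: float = 1.0
    c: float = 0.01
    alpha_0: float = 0.0
    d_B: float = 0.1
    d_W: float = 0.1
    d_Z: float = 0.1
    lam: float = 0.1
    D_W: float = 10.0
    D_Z: float = 10.0
    L_QC: float = 15.0
    alpha_S: float = 0.0
    d_S: float = 0.1
    lambda_S: float = 0.1
    D_S: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ConfigError(f"parameter {f.name!r} must be finite and >= 0, got {v}")
        if self.n < 1:
            raise ConfigError(f"Hill exponent n must be >= 1, got {self.n}")
        if self.h < 1:
            raise ConfigError(f"self-repression exponent h must be >= 1, got {self.h}")
        if self.L_QC <= 0:
            raise ConfigError("L_QC must be positive")

    @property
    def x_vi(self) -> float:
        """End of the VI region, at 3*L_QC/2."""
        return 1.5 * self.L_QC

    def with_(self, **kwargs: float) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class FullModelParams:
    """Mass-action rates of the explicit BRAVO-WOX5 complex.

    ``k_on`` is the association rate (1/(conc*time)), ``k_off`` the
    dissociation rate (1/time) and ``d_C`` the complex degradation rate
    (1/time).  The minimal sequestration model is recovered at stationarity
    with ``lambda = k_on*d_C/(k_off + d_C)``.
    """

    k_on: float = 0.1
    k_off: float = 0.0
    d_C: float = 0.1

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "d_C"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ConfigError(f"{name} must be finite and >= 0, got {v}")


def lambda_eff(fp: FullModelParams) -> float:
    """Effective sequestration rate of the explicit-complex model.

    ``k_on*d_C/(k_off + d_C)``; the irreversible non-degrading limit
    ``k_off = d_C = 0`` maps to ``k_on`` (every bound pair is removed
    permanently).  A reversible, non-degrading complex (``d_C = 0``,
    ``k_off > 0``) yields 0: it confers no confinement.
    """
    denom = fp.k_off + fp.d_C
    if denom == 0.0:
        return fp.k_on
    return fp.k_on * fp.d_C / denom


@dataclass
class ModelSpec:
    """Which model variant to run and under which switches.

    genotype "bravo" models the loss-of-function mutant: the very same
    equations and parameters as the wild type, but with ``B(x, t) = 0``
    for all x and t (the BRAVO equation is dropped).
    """

    variant: str = "sequestration"
    production_mode: str = "linear"
    wox5_self_repression: bool = False
    basal_vi_production: bool = False
    genotype: str = "wt"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.production_mode not in ("linear", "hill"):
            raise ConfigError(f"production_mode must be 'linear' or 'hill', got {self.production_mode!r}")
        if self.genotype not in ("wt", "bravo"):
            raise ConfigError(f"genotype must be 'wt' or 'bravo', got {self.genotype!r}")

    @property
    def sequestering(self) -> bool:
        return self.variant in _SEQUESTERING

    @property
    def repressing(self) -> bool:
        return self.variant in _REPRESSING

    @property
    def z_activated(self) -> bool:
        return self.variant in _Z_ACTIVATED


def species_for(spec: ModelSpec) -> Tuple[str, ...]:
    """Species integrated for this spec (the bravo mutant has no B equation)."""
    sp = _VARIANT_SPECIES[spec.variant]
    if spec.genotype == "bravo":
        sp = tuple(s for s in sp if s != "B")
    return sp


def activator_species(spec: ModelSpec) -> str:
    """The species whose concentration drives BRAVO production (W or Z)."""
    return "Z" if spec.z_activated else "W"


@dataclass
class Grid1D:
    """Uniform 1D grid.

    Default domains follow the two solver routes: the boundary-value solve
    uses dx = 0.05 on [-600, 600]; the explicit Euler route uses dx = 1 on
    [-400, 400].
    """

    x_min: float = -600.0
    x_max: float = 600.0
    dx: float = 0.05

    def __post_init__(self) -> None:
        if self.x_max <= self.x_min:
            raise ConfigError("x_max must exceed x_min")
        if self.dx <= 0:
            raise ConfigError("dx must be positive")
        n = (self.x_max - self.x_min) / self.dx
        if abs(n - round(n)) > 1e-9 * max(1.0, n):
            raise ConfigError("(x_max - x_min) must be an integer multiple of dx")

    @classmethod
    def bvp_default(cls) -> "Grid1D":
        return cls(-600.0, 600.0, 0.05)

    @classmethod
    def euler_default(cls) -> "Grid1D":
        return cls(-400.0, 400.0, 1.0)

    @property
    def n_nodes(self) -> int:
        return int(round((self.x_max - self.x_min) / self.dx)) + 1

    @property
    def x(self) -> np.ndarray:
        return np.linspace(self.x_min, self.x_max, self.n_nodes)


# ---------------------------------------------------------------------------
# regulatory functions
# ---------------------------------------------------------------------------

def _logistic(z: np.ndarray) -> np.ndarray:
    from scipy.special import expit

    return expit(z)


def qc_indicator(x, L_QC: float, w: float = 0.0):
    """1 inside the QC (-L_QC/2 <= x <= L_QC/2, boundaries inclusive), else 0.

    ``w > 0`` replaces the sharp step with a logistic transition of width w
    (used by collocation solvers, which require a smooth right-hand side).
    """
    if L_QC <= 0:
        raise ConfigError("L_QC must be positive")
    x = np.asarray(x, dtype=float)
    if w > 0:
        out = _logistic((x + L_QC / 2) / w) * _logistic(-(x - L_QC / 2) / w)
    else:
        out = ((x >= -L_QC / 2) & (x <= L_QC / 2)).astype(float)
    return out if out.ndim else float(out)


def activation_mask(x, L_QC: float, w: float = 0.0):
    """Heaviside mask for BRAVO activation: 1 for x >= -L_QC/2 (QC-to-VI side)."""
    if L_QC <= 0:
        raise ConfigError("L_QC must be positive")
    x = np.asarray(x, dtype=float)
    if w > 0:
        out = _logistic((x + L_QC / 2) / w)
    else:
        out = (x >= -L_QC / 2).astype(float)
    return out if out.ndim else float(out)


def vi_indicator(x, L_QC: float, w: float = 0.0):
    """1 on the VI region (L_QC/2, 3*L_QC/2], else 0."""
    if L_QC <= 0:
        raise ConfigError("L_QC must be positive")
    x = np.asarray(x, dtype=float)
    if w > 0:
        out = _logistic((x - L_QC / 2) / w) * _logistic(-(x - 1.5 * L_QC) / w)
    else:
        out = ((x > L_QC / 2) & (x <= 1.5 * L_QC)).astype(float)
    return out if out.ndim else float(out)


def _check_nonneg(value, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise DomainError(f"{name} must be nonnegative")
    return arr


def _hill(u: np.ndarray, vmax: float, k: float, n: float) -> np.ndarray:
    un = np.power(u, n)
    return vmax * un / (k**n + un)


def prod_bravo(activator, x, p: ModelParams, spec: ModelSpec, w: float = 0.0):
    """BRAVO production rate P_B(activator, x).

    Linear mode: ``alpha_L * activator * Theta(x + L_QC/2)``; Hill mode:
    ``alpha * a^n/(k_B^n + a^n) * Theta``.  The Heaviside mask restricts
    activation to the QC-to-vasculature side.  With basal VI production on,
    ``alpha_0`` is added on VI nodes only.  ``w`` smooths the spatial masks
    (see :func:`qc_indicator`).
    """
    a = _check_nonneg(activator, "activator")
    theta = activation_mask(x, p.L_QC, w)
    if spec.production_mode == "linear":
        out = p.alpha_L * a * theta
    else:
        out = _hill(a, p.alpha, p.k_B, p.n) * theta
    if spec.basal_vi_production:
        out = out + p.alpha_0 * vi_indicator(x, p.L_QC, w)
    return out


def prod_wox5(W, x, p: ModelParams, spec: ModelSpec, w: float = 0.0):
    """WOX5 production rate P_W(W, x): gamma inside the QC, optionally
    self-repressed by ``1/(1 + (W/k_W)^h)``."""
    Wv = _check_nonneg(W, "W")
    base = p.gamma * qc_indicator(x, p.L_QC, w)
    if spec.wox5_self_repression:
        if p.k_W <= 0:
            raise ConfigError("k_W must be positive when WOX5 self-repression is on")
        return base / (1.0 + np.power(Wv / p.k_W, p.h))
    return base * np.ones_like(Wv) if np.ndim(Wv) else base


def prod_z(W, B, p: ModelParams, spec: ModelSpec):
    """Z production rate P_Z(W, B).

    Activation by WOX5 (linear ``beta_L*W`` or Hill ``beta*W^n/(k_Z^n+W^n)``),
    multiplied in the repression and mixed variants by ``1/(1 + c*B)``;
    ``c = 0`` disables repression exactly.
    """
    Wv = _check_nonneg(W, "W")
    Bv = _check_nonneg(B, "B")
    if spec.production_mode == "linear":
        out = p.beta_L * Wv
    else:
        out = _hill(Wv, p.beta, p.k_Z, p.n)
    if spec.repressing:
        out = out / (1.0 + p.c * Bv)
    return out


# ---------------------------------------------------------------------------
# reaction right-hand sides
# ---------------------------------------------------------------------------

def model_rhs(
    state: Dict[str, np.ndarray], x, p: ModelParams, spec: ModelSpec, w: float = 0.0
) -> Dict[str, np.ndarray]:
    """Reaction part of the time derivatives for the minimal model variants.

    ``state`` maps species names to concentrations (arrays over nodes or
    scalars); diffusion is *not* included.  For genotype "bravo" the state
    carries no B; productions are evaluated with B = 0 and no dB is
    returned.
    """
    if spec.variant == "full_complex":
        raise ConfigError("use full_complex_rhs for the explicit-complex model")
    species = species_for(spec)
    for s in species:
        if s not in state:
            raise ConfigError(f"state missing species {s!r} required by variant {spec.variant!r}")
        _check_nonneg(state[s], s)

    x = np.asarray(x, dtype=float)
    mutant = spec.genotype == "bravo"
    B = np.zeros_like(x) if mutant else np.asarray(state["B"], dtype=float)
    W = np.asarray(state["W"], dtype=float)

    out: Dict[str, np.ndarray] = {}
    seq = p.lam if spec.sequestering else 0.0

    if spec.z_activated:
        Z = np.asarray(state["Z"], dtype=float)
        P_B = prod_bravo(Z, x, p, spec, w)
        out["Z"] = prod_z(W, B, p, spec) - p.d_Z * Z
    else:
        P_B = prod_bravo(W, x, p, spec, w)

    dW = prod_wox5(W, x, p, spec, w) - p.d_W * W - seq * B * W
    if spec.variant == "sequestration_S":
        S = np.asarray(state["S"], dtype=float)
        dW = dW - p.lambda_S * S * W
        out["S"] = p.alpha_S - p.d_S * S - p.lambda_S * S * W
    out["W"] = dW

    if not mutant:
        out["B"] = P_B - p.d_B * B - seq * B * W
    return out


def full_complex_rhs(
    state: Dict[str, np.ndarray], x, p: ModelParams, fp: FullModelParams, spec: ModelSpec, w: float = 0.0
) -> Dict[str, np.ndarray]:
    """Reaction terms of the explicit-complex sequestration model.

    dB = P_B - d_B*B - k_on*B*W + k_off*C
    dW = P_W - d_W*W - k_on*B*W + k_off*C
    dC = k_on*B*W - (k_off + d_C)*C
    """
    x = np.asarray(x, dtype=float)
    mutant = spec.genotype == "bravo"
    B = np.zeros_like(x) if mutant else _check_nonneg(state["B"], "B")
    W = _check_nonneg(state["W"], "W")
    C = _check_nonneg(state.get("C", np.zeros_like(x)), "C")

    bind = fp.k_on * B * W
    out = {
        "W": prod_wox5(W, x, p, spec, w) - p.d_W * W - bind + fp.k_off * C,
        "C": bind - (fp.k_off + fp.d_C) * C,
    }
    if not mutant:
        out["B"] = prod_bravo(W, x, p, spec, w) - p.d_B * B - bind + fp.k_off * C
    return out
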