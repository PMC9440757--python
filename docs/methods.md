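# Methods

## The biological problem and the models

In the Arabidopsis primary-root stem-cell niche, the transcription factor
BRAVO is expressed in the quiescent center (QC) and the vascular initials
(VI), and its expression domain *expands* in the *bravo* loss-of-function
mutant: BRAVO confines its own expression. The package implements the
reaction–diffusion models of that self-confinement. Their shared logic is
**attenuation of a mobile activator**: WOX5, produced only in the QC,
diffuses and (directly or through an intermediary Z) activates *BRAVO*;
immobile BRAVO protein attenuates the activator, either by

* **sequestration** — BRAVO and WOX5 bind into an immobile, inactive,
  degradable complex, an effective bilinear loss `λ·B·W` on both free
  concentrations; or
* **repression** — BRAVO represses the production of the mobile
  intermediary Z by the factor `1/(1 + c·B)`;

or both (**mixed** model). Two auxiliary variants complete the family: a
competing sequestrator S that also binds WOX5, and a "full" model in which
the BRAVO–WOX5 complex is explicit, with mass-action binding `k_on`,
unbinding `k_off` and complex degradation `d_C`. At stationarity the full
model reduces exactly to the minimal sequestration model with
`λ_eff = k_on·d_C/(k_off + d_C)`: a reversible complex that is never
degraded (`d_C = 0`) confers no confinement.

### One-dimensional geometry

Space is the root axis in arbitrary units (a.u.). WOX5 production `γ` is
restricted to the QC, `−L_QC/2 ≤ x ≤ L_QC/2` with `L_QC = 15` a.u.
(boundaries inclusive). BRAVO activation is allowed only shootward of
`x = −L_QC/2` (Heaviside mask, inclusive), mimicking the observed
asymmetry. The VI is `(L_QC/2, 3·L_QC/2]`, the same length as the QC.
Activations are either linear (`α_L·W`, `β_L·W`) or saturating Hill
functions (`α·a^n/(k^n + a^n)`, default cooperativity `n = 2`); WOX5
self-repression, when enabled, divides `γ` by `1 + (W/k_W)^h` with
`h = 1` by default (the half-point property `P_W(k_W) = γ/2` holds for
any `h`). The *bravo* mutant uses identical equations and parameters with
`B(x, t) = 0` for all x and t; the BRAVO *promoter activity*
`pB(x) = P_B(activator_s(x), x)` remains defined and observable.

## Stationary solvers

Two independent routes compute stationary profiles and must agree — this
cross-validation is itself a shipped test.

**Boundary-value route.** Non-diffusible species are eliminated from their
stationary relations (`B = P_B/(d_B + λW)`; a non-diffusible Z by a
monotone fixed-point iteration when repression couples it to B; a
non-diffusible W by the pointwise root of `P_W(W) = d_W·W`) and the
remaining second-order system is solved by `scipy.integrate.solve_bvp`
with zero Dirichlet boundaries on `[−600, 600]` (output step 0.05 a.u.),
the sequestrator S being periodic instead. Collocation requires a smooth
right-hand side, so inside the solver the step masks are evaluated as
logistic transitions of width equal to the grid step (0.05 a.u., two
orders of magnitude below the profile decay lengths; the induced deviation
is below 1e-5 relative and is verified against the analytic solution).
Final profiles and residuals are evaluated with the sharp masks. The
initial guess comes from a short coarse explicit integration; the solver
refines its mesh internally and reports on the user grid. Convergence
metadata (collocation rms residual, finite-difference residual of the full
system, node count) is attached to every state.

**Explicit Euler route.** Forward Euler from zero initial conditions with
the central-difference Laplacian, step `dt = 0.01`, final time 1000, grid
step 1 on `[−400, 400]`, zero boundary values. The diffusive stability
bound `dt·D/dx² ≤ 1/2` is enforced before stepping; concentrations are
clipped at zero after each step (at stable steps this only removes
roundoff-level negatives). Stationarity is assessed as the relative state
change over the last 1% of steps (warning above 1e-6).

A numerical caveat discovered during validation: on grids whose nodes hit
`±L_QC/2` exactly (e.g. dx = 0.5), the inclusive boundary nodes inflate
the discrete source integral by one cell width — a first-order error — so
the coarse dx = 1 grid, whose nodes straddle the QC boundary, is actually
the best-behaved explicit grid. The cross-route comparison is made on it.

## Observables and compatibility

For a wild-type/mutant pair, with `pB* = pB_wt(x_VI)`:

* `Δx` = rightmost crossing of the mutant pB profile with `pB*` (linear
  interpolation on the decaying tail) minus `x_VI`; `ξ = Δx/L_QC`.
* `R_B = pB_mut(0)/pB_wt(0)`, `R_BW = pB*/pW_wt(0)`,
  `R_W = pW_mut(0)/pW_wt(0)` (reported only when BRAVO feeds back on the
  WOX5 promoter, i.e. sequestration with self-repression).

"QC center" is the point value at x = 0. A parameter set is *compatible*
with the experimental observations when `ξ ∈ [0.5, 5]`, `R_B ∈ [1, 2]`,
`R_BW ∈ [0.05, 0.5]` and, when applicable, `R_W ∈ [0.5, 0.9]` (all
inclusive). Scans evaluate 15×15 log-spaced parameter pairs through the
Euler route with `t_final = 300` (≥ 30 relaxation times at the shipped
degradation rates ~0.1/time) and a per-cell time step capped at
`0.45·dx²/max(D)` — the exact bound 0.5 is marginally stable and leaves
an undamped grid-scale mode. Solver failures mark a cell incompatible
with a recorded reason, and the scan continues.

## Default parameter sets

The source parameter tables are not distributed, so the shipped defaults
are the package's own, chosen (by coarse sweeps over the observables) so
that each variant's default lies inside the compatible region and the two
solver routes agree to well under 1% on the coarse grid:

| variant | key values |
|---|---|
| sequestration (linear) | α_L=0.2, γ=1, d_B=d_W=0.1, λ=0.1, D_W=10 |
| sequestration+Z (Hill, self-repr.) | α=0.3, k_B=0.2, β=1, k_Z=1, k_W=5, λ=0.3, D_W=D_Z=6, d_W=0.05, d_Z=0.1 |
| repression (Hill) | α=0.5, k_B=0.2, β=1, k_Z=1, c=1, D_W=2, D_Z=12, d_Z=0.05 |
| mixed (Hill, self-repr.) | sequestration+Z values with c=0.1 |

Degradation rates ~0.1/time set relaxation times ~10, and `√(D/d)` decay
lengths of 5–15 a.u. — comparable to the QC length, as the confinement
mechanism requires. Very steep activation (k_B = 0.1) was rejected for
the 1D defaults because it amplifies coarse-grid truncation beyond the 1%
cross-validation band.

## Synthetic root layouts and segmentation

The original propidium-iodide confocal midplanes are not distributed, so
`layout.generate_layout` builds a stylized stand-in: vertical tissue files
(lateral root cap, epidermis, cortex, endodermis, pericycle, vasculature)
with per-file cell rows, a QC row flanked shootward by VI and rootward by
columella stem cells and columella tiers, all walls exactly 2 px wide,
root outline included in the single wall label, lattice 228×448 px
(wild type) or 231×448 (mutant), 1 px ≈ 0.5 μm. The geometry is
deterministic; the seed only drives the noise of the rendered wall-stain
image (bright walls, dim interiors, dark background, Gaussian noise
σ = 6 at a wall/interior contrast of 140).

`segment_image` recovers the labels from such an image: global Otsu
threshold → wall mask; skeletonization re-thickened to the fixed 2-px
width by intersecting a 3×3 dilation of the skeleton with the thresholded
mask (this pins the wall onto the stained pixels and suppresses isolated
noise); 4-connected component labeling (4-connectivity prevents diagonal
leaks through 2-px walls); border-touching components merge into the
single outside label; regions under 4 px merge into the wall with a
warning. On generator output the round trip recovers the exact cell count
and > 99% pixel-class agreement up to at least noise σ = 25 at the default
wall/interior contrast of 140 (the shipped default is σ = 6); the
mask-guided re-thickening is what makes the walls land exactly on the
ground-truth pixels.

What the synthetic layouts do **not** emulate: curved or irregular cell
walls, cell-size gradients along the axis, intensity inhomogeneity and
depth-dependent attenuation of real confocal images. Passing the
round-trip tests therefore demonstrates the correctness of the
segmentation pipeline's mechanics, not its robustness on real microscopy.

## 2D pixel-grid simulation

The mixed model runs on the layout lattice with a forward-time
central-space scheme, dt = 0.1, default final time 3000. Diffusion is
heterogeneous: each species has a cytoplasmic coefficient on cell pixels
and a smaller one on wall pixels, zero outside the root. The conservative
flux form uses arithmetic-mean face diffusivities, forced to zero when
either face pixel has zero diffusivity — this makes the root border
exactly reflecting, and total mass is conserved to machine precision
under pure diffusion (a shipped test). Reactions run on cell pixels only;
inside walls molecules only diffuse. BRAVO (and implicitly the complex)
has zero wall diffusivity. WOX5 production is restricted to QC cells;
activator-driven BRAVO production to QC, VI, vascular, cortex and
endodermis cells; basal BRAVO production to template-designated VI cells.
Each promoter drives a GFP reporter with the same production term; all
reporters share one diffusion coefficient and one degradation rate. The
mutant holds B at zero while the BRAVO reporter keeps evolving.

Default 2D transport (px²/time): `D_W` 1.0 (cyt) / 0.02 (wall), `D_Z`
1.0 / 0.8, `D_B` 0.3 / 0, GFP 0.5 / 0.03, `d_GFP` = 0.1; kinetics as the
mixed 1D set but with λ = c = 1, k_B = 0.1, d_Z = 0.01 and basal
α₀ = 0.02. The slow wall crossing for WOX5 keeps > 80% of its mass in the
QC+VI+CSC region when all regulation is off; the long-lived, wall-permeable
Z carries activation shootward, and sequestration plus repression confine
it in the wild type — the mutant's transversally integrated BRAVO-reporter
profile dominates the wild type's on every row shootward of the VI and its
shootward half-maximum moves at least one vascular cell row farther.

**Resolution caveat.** Walls are always 2 px wide, so on coarse lattices
with small cells the wall compartment (which has no degradation) becomes a
disproportionate reservoir. The reduced test lattice
(`LayoutTemplate.small`, 100×200 px) therefore uses fewer, larger cells
rather than a uniform shrink of the full template, preserving a realistic
cell-interior/wall area ratio. Tests and the acceptance script run the 2D
model on this lattice at t = 1000 (profiles are unchanged from longer
runs at the shipped rates); the packaged `mixed2d` configuration keeps the
full 228×448 template and t = 3000.

## Known limitations

* No transcription/translation delays, no stochastic dynamics, no 3D.
* Scan heatmaps are structurally faithful (axes, observables, masks), not
  pixel-faithful reproductions of any published figure, because the source
  parameter tables are not available.
* The BVP route does not support eliminating a non-diffusible WOX5 in
  sequestering variants (the elimination is no longer explicit); the Euler
  route covers that corner.
* The explicit-complex model with `k_off = d_C = 0` has no stationary
  state (the complex accumulates indefinitely); the BVP route refuses it.
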