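# Methods

## Model overview and assumptions

The simulator couples two phase fields, two reaction–diffusion species and a
set of discrete agents on a rectangular tissue domain:

* the **tumor** φ marks malignant tissue (φ = 1) against host tissue
  (φ = 0) and evolves by non-conserved (Allen–Cahn) gradient dynamics of a
  tilted double-well free energy.  The model assumes a compact,
  non-invasive lesion whose dynamics is concentrated at the thin interface
  between tumor and host, and that local nutrient availability alone decides
  whether the interface advances or retreats: the tilt
  m(σ) = −(2/D)·arctan(15(σ−σ^h−v)) with D = 3.01π changes sign at the
  hypoxic–viable threshold.  |m| < 1/3 everywhere, so both bulk states stay
  local minima of the potential for every nutrient level — host and tumor
  phases never lose metastability, only their relative depth changes.
* the **capillary field** c marks vessel lumen (c = 1) against avascular
  tissue (c = −1) with conserved (Cahn–Hilliard) dynamics plus a
  non-conserved endothelial proliferation source B_p(f)·cH(c) that is only
  active inside vessels and saturates at TAF level f_p.  Stalk-cell
  proliferation is therefore a continuum process; only tip cells are
  discrete.
* **nutrient** σ is produced inside capillaries at a rate scaled by the
  network functionality S and proportional to (1−σ), diffuses, and is taken
  up ten times faster by tumor than by host tissue.  σ stands for whichever
  transported species limits growth (oxygen, glucose); no distinction is
  made.
* **TAF** f lumps all pro- minus anti-angiogenic signaling into one field
  secreted by hypoxic tumor cells — the secretion rate G(σ) is a Gaussian
  bump of width 1/√250 centered midway between the necrotic–hypoxic and
  hypoxic–viable thresholds — and consumed by capillaries.
* **tip endothelial cells (TECs)** are circular agents of radius R.
  Activation requires a capillary point (c ≥ c_act), enough TAF
  (f ≥ f_act), and — the Dll4/Notch lateral-inhibition surrogate — distance
  > δ₄ to every active tip cell.  If several grid nodes qualify in a step,
  one is chosen uniformly at random; this is the model's only stochastic
  element.  Active cells migrate with velocity χ·(∇f/|∇f|)·J(φ), where
  J(φ) = 0.45[tanh(50(0.5−φ))+1]+0.1 slows intratumoral migration tenfold.
  Once a cell has migrated 4R from its parent vessel it probes c at
  filopodia sample points; a positive sample redirects the cell toward the
  detected capillary, and fusion (anastomosis) deactivates it.  Each cell is
  stamped into c every step as a radial template, max(c, tanh((R−r)/ε)),
  leaving a trail the proliferation term sustains.

The vasculature is additionally tracked as a segment list: the parent
vessel (length = quarter-domain width) plus one sprout per activation whose
length is the cell's accumulated arc length.  The functionality statistic
S = l_max/Σ l_i feeds back into nutrient production; a skeleton-based
measurement (threshold c > 0, skeletonize, split at branch points) provides
an independent cross-check of the tracked lengths at topology level.

## Geometry and scenarios

Simulations use the quarter domain Ω_q (1312.5 µm × 1012.5 µm = 1050 × 810
length units) of a symmetric tissue: the tumor disc (radius 625 µm, with a
concentric necrotic core of radius 0.45·625 µm where σ = 0) is centered at
the top-left corner, a capillary strip 25 µm wide runs along the bottom
edge (c = 1, σ = 1), and σ = 0.45 elsewhere.  Zero-flux boundaries realize
both the symmetry planes (left, top) and tissue isolation (right, bottom).
Initial interfaces are smoothed tanh profiles rather than jumps to avoid
first-step stiffness.  The initial σ = 1 strip is an initial condition
only; the production term, not a Dirichlet constraint, maintains the
capillary nutrient level thereafter.

Four scenario modes: `avascular` (c and f frozen, no TEC activation,
S ≡ 1), `vascular` (full model, δ₄ = 80), `dll4_blockade` (δ₄ = 55,
emulating Notch down-regulation), and `small_spheroid` (tumor three times
smaller).  Horizons default to 1054 days (avascular) and 5.1 days
(vascular-type); one day is 86400/1562.5 = 55.296 time units.

## Parameters

All quantities are nondimensional with length scale L = 1.25 µm and time
scale T = 1562.5 s.  Defaults (see `ModelParameters`): M_φ = 0.3,
λ_φ = 22, D_σ = 30, V_p^c = 1, V_u^T = 6×10⁻³, V_u^H = 6×10⁻⁴,
σ^n−h = 0.2, σ^h−v = 0.4, f_p = 0.3, M_c = 1, λ_c = 1, B_p = 1.401, R = 4,
c_act = 0.9, f_act = 0.001, χ = 7.28, δ₄ = 80, D_f = 100, B_u = 6.25.
Derived scales worth knowing: the host-tissue nutrient decay length is
√(D_σ/V_u^H) = 223.6 units ≈ 280 µm, which places the σ = 0.4 contour
roughly 200–260 µm from the parent vessel — the classical hypoxia
distance; the TEC speed χ corresponds to ≈ 0.35 µm/min.

Constants the equations need but that have no canonical value are exposed
on `ModelParameters`: the smoothed-Heaviside half-width `eps_H` = 0.1
(H(x) = ½(1+tanh(x/eps_H)), so cH(c) approximates the positive part of c);
the TAF secretion amplitude `G_amp` = 0.02/√(2π) ≈ 7.98×10⁻³ (read as a
Gaussian-normalization remnant); the template interface width
`eps_template` = 1; and the tilt denominator `m_denominator` = 3.01π
(anything > 3π keeps |m| < 1/3).

### A note on the tumor interface kinetics

With the default mobility and interface constants the tilted Allen–Cahn
front moves at speed v ≈ (6/√2)·M_φ·λ_φ·m(σ) ≈ 28·m(σ) length units per
time unit (verified in the test suite against a fine-grid explicit
integration).  At the nutrient levels that the transport balance actually
produces in the tissue (σ ≈ 0.1–0.3 beyond the hypoxia distance), this is
several hundred µm/day: an avascular lesion first overshoots its initial
area by roughly a third while the background nutrient lasts and then
regresses completely within a few simulated days, and in the vascular
scenario the lesion is gone before the (correctly timed, ~day 2–3)
angiogenic sprouts arrive.  Slow multi-month dormancy would require an
interface mobility orders of magnitude smaller — but then the early
transient would vanish too; no single constant reconciles both regimes.
The package keeps the reference constants as given and reports what they
produce; `M_phi` and `lambda_phi` are ordinary config parameters for anyone
wanting slower interface kinetics, and the angiogenesis half of the model
(TAF transport, activation timing, network morphology, the Dll4 ordering)
is insensitive to this choice.

## Numerics

* **Grid**: cell-centered uniform finite differences; mirror (zero-flux)
  boundaries on all edges.  The 5-point Laplacian with these boundaries is
  diagonalized exactly by the type-II DCT, so all implicit solves are exact
  solves of the discrete system at FFT cost.  Default production grid
  512 × 396 (spacing ≈ 2 units, resolving λ_c = 1 marginally and λ_φ = 22
  comfortably); tests run at 64 × 48 to 256 × 198.
* **Tumor**: linearly stabilized IMEX — implicit diffusion and a
  stabilization shift s = 2 ≥ max|Ψ″|/2, explicit potential derivative.
  The scheme decays the discrete free energy at frozen σ for any step size
  (asserted over 100+ steps in the tests, using the forward-difference
  surface energy whose variational derivative is exactly the discrete
  Laplacian).
* **Capillaries**: implicit biharmonic + Laplacian stabilization (s = 2),
  explicit chemical potential and proliferation.  With proliferation off
  the zero mode is untouched, so ∫c is conserved to round-off.
* **Nutrient/TAF**: the reaction du/dt = a(1−u) − bu is linear in u
  pointwise, so it is advanced by its exact exponential solution, followed
  by implicit diffusion; both stages satisfy a discrete maximum principle
  and keep σ, f ∈ [0, 1] up to round-off (overshoot beyond 10⁻⁹ is an
  error, smaller residue is clipped).  The indicator cH(c) is clamped at
  zero: its smoothed negative lobe (≈ −0.01 at the vessel wall) would
  otherwise act as a spurious source/sink.
* **Step-size control**: reject-and-halve when any field changes by more
  than 5×10⁻² in max norm in one step, grow by 1.2× below 5×10⁻³, bounds
  [10⁻⁴, 5]; additionally dt ≤ R/(2·max TEC speed) so no agent moves more
  than half its radius per step.  Step order: nutrient → tumor → TAF →
  capillaries → agent moves/imprints → anastomoses → activation scan →
  network update.
* **Agents on coarse grids**: the stamped template radius and width are
  floored at ~1.5 grid spacings so a sprout is always at least one cell
  wide; on production grids the floor is inactive.  Filopodia are K = 16
  probes at radii {2R, 4R} on rays every 45°, skipping a ±60° trailing
  cone and any point within 1.5R of the cell's own recent path (last 8R of
  arc) — self-detection of the trailing sprout is excluded by
  construction.  Anastomosis uses forward probes at 1.6R in a ±75° cone
  around the redirect direction with the same trail exclusion; probing
  (rather than testing the raw c value under the cell) is required because
  the cell's own imprint saturates c at its center every step.  A cell
  deactivates on anastomosis, on reaching a domain edge, or after 10
  consecutive steps with f < f_act at its center (hysteresis against
  flicker).  Whether a closed sprout may later host a new activation is
  left to the activation conditions themselves (it may).
* **Determinism**: one seeded generator drives the single stochastic
  operation (the activation tie-break); identical configurations reproduce
  results bit for bit.

## Observables

Tumor area is the area of {φ > 0.5}, measured by counting on a 4× bilinear
refinement of the field (sub-cell resolution of the contour); capillary
area uses {c > 0}.  The threshold rule (rather than ∫φ) makes the
equivalent-radius ratio √(A_t/A_0) well defined; the rule is recorded in
each run manifest.  Inside the tumor mask, σ < σ^n−h is necrotic,
σ^n−h ≤ σ < σ^h−v hypoxic, σ ≥ σ^h−v proliferative; the three masks
partition the tumor exactly.  The hypoxia distance samples σ along the
outermost grid column (host tissue far from the tumor), from the strip's
inner boundary to the linearly interpolated first crossing of σ^h−v.  All
areas refer to the quarter domain; ratios are quadrant-invariant.

## What the scenario generator does and does not emulate

The built-in initial conditions reproduce an idealized laboratory setup: a
perfectly circular lesion, one straight parent vessel, uniform background
nutrient, no TAF at t = 0.  Real tissue adds vessel tortuosity and
hierarchy, interstitial-pressure effects, heterogeneous perfusion,
lymphatics, immune and stromal interactions, and 3D geometry — none are
modeled.  Passing tests therefore demonstrate internal consistency of the
model and solver (conservation, energy decay, symmetry, reproducibility,
parameter-ordering effects such as the Dll4 comparison), not quantitative
agreement with any particular in vivo system.

## Problem sizes used by the shipped checks

The acceptance script runs the avascular scenario at 128 × 99 (day-1054
horizon, plus a finely sampled two-week run for the early transient) and
the vascular scenario at 256 × 198 over three seeds; the test suite's
Dll4 comparison uses five paired seeds at 128 × 99.  These resolutions
keep the full set of checks within a few minutes on one CPU while
resolving the capillary strip (2+ cells) and the tumor interface (7+
cells); the grid-convergence test verifies that halving the spacing moves
the early tumor area by < 2 %.

## Known limitations

* The reference interface constants produce fast tumor-front kinetics (see
  the note above): avascular simulations end in extinction rather than
  multi-month dormancy, so long-horizon area ratios are degenerate.
* 2D only; the quarter-domain symmetry forbids asymmetric network
  morphologies.
* λ_c = 1 interfaces are marginally resolved on desk-scale grids; capillary
  area at coarse resolution is systematically thicker (template floor).
* The segment bookkeeping never merges segments at anastomosis (n stays
  the number of activations + 1); S is therefore a lower bound relative to
  a decomposition that merges loops.
* First-order time accuracy; the adaptive controller targets robustness,
  not high-order error control.
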