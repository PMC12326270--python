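# Methods

## Take-off kinematics

A take-off is an ordered track of 3D positions (metres) at frame rate `fps`
(default 60 frames s⁻¹). Speed is the backward finite difference
`v[n] = ‖r[n] − r[n−1]‖ · fps`; the first frame's speed is therefore
undefined and every analysis window starts at frame 1 or later. For
quadratic (ballistic) motion this difference equals the true speed at the
interval midpoint exactly, so per-frame total mechanical energy
`½mv² + mgz` is conserved up to an O(Δt) discretisation term — the test
suite verifies the term shrinks as the frame rate doubles.

Choices the underlying measurement protocol leaves open, and how they were
fixed here:

* **Onset.** The averaging window starts at the first frame whose speed
  exceeds a threshold (default 0.5 m s⁻¹) and that is followed by a full
  window. Threshold and window length (default 10 frames) are configurable
  because how the averaged frames are anchored to perch departure is an
  open question of the protocol.
* **Height datum.** z is referenced to the onset frame, making potential
  energy zero at onset and the result invariant under rigid translation and
  rotation about the vertical — a property tested directly.
* **Smoothing.** None by default (differencing raw coordinates); a width-3
  moving average is available but off, so users quantify rather than assume
  the effect of coordinate noise.
* Gravity is g = 9.80665 m s⁻² everywhere.

## Respirometry

Concentration is in µM (≡ nmol ml⁻¹); a flux f pmol s⁻¹ ml⁻¹ produces a
slope of −f/1000 µM s⁻¹. Each state's flux is the negative least-squares
slope over the **last 60 s of its protocol segment**, provided the segment
lasts at least settle (30 s) + window (60 s); the settle time lets the
post-titration transition decay (the simulator's transition time constant
is 15 s, so 30 s leaves < 15% residual at window start and < 0.3% at the
window's weighted centre; round-trip tests confirm < 1% error). Both
settle and window are configurable — the instrument protocol does not
prescribe a window policy.

* ROUTINE is read from the window ending at the pyruvate event; the
  post-pyruvate segment is measured and reported as an auxiliary state but
  excluded from all derived quantities.
* ETS is the **maximum** single-plateau flux across CCCP steps, matching a
  titration driven until maximal uncoupled respiration, not a plateau mean.
* Non-mitochondrial flux (post-antimycin) is subtracted from every other
  state; corrected rates are rescaled by chamber volume / blood volume
  (default 2 ml / 50 µl: 50 µl blood diluted in 0.95 ml medium, added to a
  chamber holding 1 ml — both volumes user-overridable and recorded in the
  output metadata, since the assay description admits other readings).
* Negative corrected rates are **retained and flagged**, never clamped:
  clamping would bias the flux control ratios. Samples with non-positive
  ROUTINE (or ETS) get no ratio, only a flag, and are dropped with a logged
  count by the statistics stage.
* Blood cell count is carried as a model covariate only; rates are expressed
  per µl blood, not per cell.

## Cohort generator

The generative model is the minimal structure consistent with the fitted
linear models downstream:

* (ROUTINE, LEAK, ETS) are multivariate Gaussian. ROUTINE–ETS correlation
  defaults to 0.8 ("strongly correlated" predictors); LEAK correlates at
  0.2 with both, reflecting its lack of an endurance relationship. OXPHOS,
  coupling efficiency and reserve capacity are derived per individual.
* endurance = intercept + 3.858·ETS + 15.583·mass + ε, truncated to
  [20, 411] s. The defaults for slopes, endurance mean (163.8 s) and sd
  (85.39 s) and the R² target (0.29) are the study conditions the generator
  emulates.
* take-off energy, body mass and blood cell count are drawn independently
  of everything mitochondrial; the take-off arm is a built-in null with
  effect fixed at zero, so type-I error calibration is testable.

No marginal means/SDs or a correlation matrix are published for the
predictors, so the marginals are **placeholders chosen for physiological
plausibility**, not estimates: ROUTINE 15 ± 4, LEAK 3 ± 1, ETS mean 30
(pmol O2 s⁻¹ µl⁻¹; coupling efficiency then centres near 0.8), body mass
27.5 ± 1.5 g, blood cells 3.5×10⁶ ± 5×10⁵ µl⁻¹, take-off energy
0.14 ± 0.03 J.

Two calibration details matter for parameter recovery:

1. **Truncation without bias.** Naively redrawing ε until endurance lands in
   [20, 411] makes E[ε | predictors] depend on the linear predictor and
   attenuates the fitted slope by ~5%. Instead ε is drawn from a truncated
   Gaussian on [20 − μᵢ, 411 − μᵢ] whose location is solved (vectorised
   bisection on the truncated-normal mean) so that E[ε] = 0 exactly. The
   conditional endurance mean is then exactly linear and the OLS slope is
   unbiased — the recovery tests rest on this. Individuals whose μ falls
   outside (25, 406) s admit no mean-zero residual and are redrawn
   (probability ~10⁻³ at defaults; shifts the ETS mean by ≈ +0.07 and the
   endurance grand mean by ≈ +0.3 s, inside the acceptance bands).
2. **R² calibration.** The ETS spread and residual scale are derived, not
   free: the target is the *expected fitted* R² of the three-predictor model
   at cohort size n, so the population value is deflated by the
   finite-sample inflation E[R²] ≈ 1 − (1 − ρ²)(n − p − 1)/(n − 1) with
   p = 3, and the residual draw scale is solved (Gauss–Hermite quadrature
   over the linear predictor plus 1-D root search) so that the *average
   post-truncation* residual variance matches. With the defaults this
   reproduces both the endurance sd and a mean fitted R² within ~0.01 of
   the 0.29 target; truncation makes residuals mildly heteroscedastic,
   which OLS point estimates tolerate (and which is why the homoscedastic
   diagnostics null is exercised on constructed tables, not cohorts).

The trace generator declines piecewise-linearly at the active state's flux
with an exponential transition (τ = 15 s) after each event, integrated in
closed form; CCCP step fluxes rise linearly from midway between LEAK and
the peak, hit the peak at step max(1, k − 1), then decline 10% per later
step, so maximum-detection logic always has a descent to reject when k ≥ 2.
The trajectory generator is exact ballistic motion (optionally preceded by
stationary perch frames) plus i.i.d. Gaussian coordinate noise. All three
generators are deterministic given their seed.

What the generators do **not** emulate: videogrammetry reconstruction error
structure (noise is i.i.d., real triangulation error is not), instrument
drift and background-flux calibration of the respirometer, non-Gaussian
predictor tails, and any causal structure beyond a single linear
endurance link. Passing tests therefore validate the *estimators and
pipeline plumbing* under the stated statistical assumptions, not the
field-data conclusions themselves.

## Statistics

Models are ordinary least squares with an intercept: one mitochondrial
predictor at a time plus body mass and blood cell count, both always
included. Partial F for the single-df mitochondrial term is (b/SE)² (an
identity asserted on every fit); p-values are two-sided; the reported R² is
the full-model coefficient of determination; no multiple-testing
correction is applied and the run report states how many models were
fitted. Assumption checks are the closed-form equivalents of
simulation-based residual diagnostics: Shapiro–Wilk on residuals,
Breusch–Pagan against the model exog, and a |t| > 3 studentized-residual
outlier count. Influence uses Cook's distance with the conventional 4/n
threshold (configurable); exactly one row — the largest flagged D — is
removed for the refit, and the change is classified as
unchanged / weakened / reversed at α = 0.05.

Numerical conventions: rank deficiency raises rather than silently
dropping a column; zero-variance variables are named in their error;
residuals are declared degenerate (tests skipped) when their range is
below 10⁻¹⁰ of the fitted-value scale; all reports are deterministic
functions of the input table.

## Problem sizes

The replicate studies use 500 cohorts for slope/R² recovery and CI
coverage, 200 for the endurance-mean calibration, and 1000 for type-I
error rates — sizes at which the Monte-Carlo standard errors (≈0.05 on the
slope mean, ≈0.7% on rejection rates) are small relative to the bands
being checked, while a full run stays in the seconds-to-minutes range.

## Known limitations

* The one-MC-SE band on mean-slope recovery is a 68% interval around an
  unbiased estimator, so individual seed sequences can land outside it
  without indicating bias; the 3000-replicate check puts the bias at
  0.01 ± 0.02 s per pmol O2 s⁻¹ µl⁻¹.
* Breusch–Pagan power at n = 53 with two covariates saturates near 0.86
  even for strong variance gradients.
* The respirometry stage assumes the written titration order; instrument
  exports with re-oxygenation events or repeated oligomycin doses are out
  of scope, as are permeabilized-cell protocols.
* Endurance is modelled as Gaussian-with-truncation; real times-to-
  exhaustion are arguably better served by survival models, which the
  linkage analysis deliberately does not use.
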