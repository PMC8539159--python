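# Methods

## Signal model and processing chain

The measured quantity is the force each leg applies perpendicular to an
instrumented kayak footrest, one load cell per side, sampled at 1000 Hz,
with boat velocity from a GPS unit in km/h.  Paddling is cyclic: the legs
push alternately, in phase with the paddle strokes, so each channel shows a
sinus-like train of pushes riding on a small residual pre-load from the
foot strap.  One *stroke cycle* is defined from one left-footrest force
peak to the next and contains one left and one right push; the *stroke
rate* counts pushes on both sides, so a cycle at 125 strokes/min lasts
2·60/125 = 0.96 s.

Processing steps, in order:

1. **Filtering.** Each channel is low-pass filtered with a 4th-order
   Butterworth at a 20 Hz cutoff.  The filter is applied forward-backward
   (zero-phase), the de-facto standard for biomechanical signals, because
   peak *timing* defines the cycle boundaries and must not be shifted.
   The effective amplitude response is therefore the squared single-pass
   magnitude, (1 + (f/20)⁸)^(-1); the tests check the measured gains at
   5 Hz and 100 Hz against this closed form.
2. **Peak detection** uses local-maximum search with two guards: a minimum
   same-side separation defaulting to 60/(2·200) = 0.3 s (one push period
   at a 200 SPM ceiling, above any plausible sprint stroke rate) and a
   minimum topographic prominence defaulting to 25% of the channel's 95th
   percentile (absolute floor 1 N so a flat trace yields no peaks).  Both
   are configurable.
3. **Segmentation** cuts the trace at consecutive left-side peaks; the
   cycles tile the span between the first and last left peak exactly.
4. **Cycle selection.** Fifteen cycles are averaged.  Which fifteen is a
   genuine choice: the package defaults to the *last* 15 complete cycles
   of the bout, the steadiest regime after the rolling start, with a
   configurable offset.  (An analysis window that instead includes the
   acceleration phase gives systematically different absolute forces;
   comparisons across conventions should not be over-read.)
5. **Normalization.** Each selected cycle is resampled by linear
   interpolation onto a 101-point 0–100% grid (the convention for
   cycle-normalized biomechanics) and the pointwise ensemble mean and
   population SD are reported per side.  The left peak anchors 0%; the
   right peak falls near 50% in a symmetric stroke.

## Feature definitions

Over a 10-s analysis window (default: the last 10 s, matching the cycle
selection; configurable):

* **stroke rate** = (left + right peaks in window) · 60 / window length;
* **mean force** = time-average of (left + right)/2, troughs included —
  averaged across sides rather than summed so that
  2 · mean force · cycle duration ≈ impulse per cycle;
* **peak force** = mean over the analysed cycles of each cycle's per-side
  maxima, both sides pooled;
* **impulses** use the trapezoid rule per channel and sum left + right,
  once per stroke cycle (reported as the mean over analysed cycles) and
  once over the 10-s window.

## Regression models

All fits are ordinary least squares (via statsmodels).

* **Prediction.** Velocity on a subset of the five force characteristics,
  chosen by exhaustive search over all non-empty subsets minimizing
  BIC = n·ln(RSS/n) + p·ln(n), with p counting intercept and slopes;
  ties break toward fewer predictors, then lexicographically.  Any
  monotone-equivalent BIC variant selects the same subset.  Candidate
  collinearity is screened with a Pearson correlation matrix
  (zero-variance variables are flagged as missing, not silently zero).
* **Validation.** Seeded 5-fold cross-validation with random folds whose
  sizes differ by at most one; the prediction-error SD is the sample SD
  of held-out (observed − predicted).  The source analysis's phrase for
  this procedure ("leave-one-out five-fold") is contradictory; the
  five-equal-groups reading is implemented, and a true leave-one-out mode
  is available via `loo=True`.
* **Explanatory fits.** Each force characteristic regressed on velocity;
  the *adjusted* variant adds paddler group (age/sex level) as a
  dummy-coded categorical, the implemented reading of adjustment "for
  kayak level".  (A joint-feature reading is possible but is not what the
  group covariate models; nothing here claims which the original analysis
  used.)
* **Uncertainty.** Normal-theory 95% CIs from the OLS fit, plus
  case-resampling bootstrap percentile CIs (default 1000 replications,
  seeded; rank-deficient resamples are redrawn, at most 10 times).  The
  bootstrap refits use a direct least-squares path since only the
  coefficients are needed per resample.
* **Diagnostics** are numeric tables sufficient to draw the standard
  plots: residual-vs-fitted pairs, ordered residuals against normal
  quantiles, Cook's distance and leverage per observation, and residuals
  grouped by paddler (the three bouts per paddler make a correlated
  design, which is diagnosed but deliberately not modelled with random
  effects).
* No multiple-testing correction is applied; p-values are reported raw.

## Synthetic generator

`synth` stands in for the non-public on-water recordings.

* **Force sessions**: each push is a half-sine of amplitude
  (push_peak − baseline) above the baseline, occupying a duty fraction
  (default 0.85) of its half-cycle; the right train is offset by half a
  cycle.  The half-sine gives closed-form truth — area 2Aw/π per pulse —
  from which the generator reports true mean force, per-cycle impulse,
  10-s impulse (per-cycle impulse scaled by 10 s/cycle, exact when the
  window holds whole cycles), peak forces and peak times.  Defaults
  emulate the maximal-effort regime: 125 SPM, ~400 N peaks, 20-s bouts.
  The baseline defaults to 20 N so the troughs are non-zero as in real
  strapped-foot traces; no trough level is reported for the original
  data, so this is a modelling choice.  Noise is additive i.i.d.
  Gaussian — adequate because the 20 Hz filter removes it — and seeded,
  so identical specs give bit-identical traces.
* **Velocity traces**: a linear ramp (rolling start) to a plateau at the
  target velocity plus Gaussian noise, 1 Hz GPS-like sampling.
* **Cohorts**: either predictors drawn from independent normals at the
  maximal-effort scale (means/SDs ≈ 398 ± 106 N, 2384 ± 87 N·s,
  125 ± 12 SPM) with velocity from a stated linear map plus Gaussian
  residual, or velocity drawn U(12, 20) km/h with features linear in
  velocity — the two regimes of the predictive and explanatory models.
  True coefficients are stored with the table for recovery tests.

What the generator does **not** emulate: left/right asymmetry beyond
independent peak amplitudes, stroke-to-stroke variability in timing or
amplitude, leg-pull (negative) forces, drift or load-cell offset, and the
correlated three-bouts-per-paddler structure of real cohorts.  Passing
recovery tests therefore demonstrate correctness of the computations
under the stated signal model, not robustness to every artefact of real
on-water data.

## Numerical choices and degenerate inputs

* Impulse integration is the trapezoid rule on the native 1000 Hz grid;
  tests bound the error against a 30×-refined Riemann-sum oracle at 0.1%.
* A constant response makes R² undefined; it is reported as 0 by
  convention and all slopes as 0.
* Rank-deficient designs raise an estimation error naming the collinear
  columns; during BIC search such subsets are skipped with a warning.
* Readers reject malformed files (missing columns, non-monotone or
  non-uniform time) rather than coercing; feature tables are written at
  17 significant digits and parsed with round-trip float precision so
  writer/reader pairs are lossless.
* Fewer than 15 available cycles triggers averaging over all of them with
  an `underpowered` flag rather than an error.

## Problem sizes

Recovery simulations use n = 10,000 paddlers for the 1%-tolerance
coefficient checks (Monte-Carlo SE well below the tolerance), n = 200 with
100 seeded replicates for selection-consistency and CI-coverage suites,
and 20-s sessions at 1000 Hz for the signal chain — the bout length the
maximal-effort protocol uses.

## Known limitations

* The original per-bout windowing cannot be recovered from the published
  summary statistics; the fixed-velocity rows of the published feature
  table are mutually inconsistent under any single mean-force/impulse
  convention, so absolute agreement with those rows is not a test target.
* Whether the original 20 Hz filter was zero-phase, and its peak-detection
  criteria, are unreported; the defaults here are stated choices.
* The repeated-measures structure (three bouts per paddler) is diagnosed
  via per-paddler residuals but not modelled.
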