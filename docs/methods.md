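# Methods

`enamelseason` reconstructs the seasonal cycle of environmental-water
δ¹⁸O from serially drilled tooth-enamel phosphate profiles. This note
documents the models, the defaults and why they hold, the numerical
choices, and what the synthetic-data tests do and do not demonstrate.

## Water → enamel conversion

Predicted enamel phosphate for an evaporation-insensitive mammal
drinking water of composition δ¹⁸O_w (‰ V-SMOW):

    δ¹⁸O_PO4* = 0.9 · δ¹⁸O_w + 23

The coefficients are the empirical mammal-enamel calibration and are
exposed in configuration (`ConversionConstants`) but default-locked.
Carbonate values reported on V-PDB convert to V-SMOW through the
standard Coplen transform `1.03091 · δ + 30.91`; the transform constants
are likewise configurable because laboratories occasionally normalize
differently. Operations never round internally; one-decimal rounding is
presentation-layer only.

## Forward model of enamel time-averaging

Enamel mineral at axial position *x* accumulates in two stages: a
fraction `fi` arrives with the secreted matrix as the appositional front
(axial extent `la`) passes, and the remaining `1 − fi` is added while a
length `lm` of crown matures behind the front. A drill bit of width
`sample_length` integrates over the crown axis, and drilling a fraction
`depth_fraction` of the enamel thickness intersects the same fraction of
the slanted front's axial extent (an approximation — the front is
treated as linear in depth). The measured value at a sample center is
therefore a weighted average of the primary signal over a one-sided,
rootward-extending window:

* uniform window of width `la · depth_fraction`, total weight `fi`;
* uniform window of width `lm`, total weight `1 − fi`;
* both convolved with a centered uniform window of width `sample_length`.

Kernels extend rootward because maturation mineral is added *after* the
front passes; positions are stored occlusal → root with time increasing
rootward. Root-referenced coordinates are converted at I/O.

Defaults: `la = 7` mm (midpoint of the 2–12 mm range reported for small
bovids), `lm = 13.3` mm, `depth_fraction = 0.75`, `sample_length = 2`
mm, `growth_rate = 30` mm/yr. `fi = 0.25` is a conventional initial
mineral content for ungulate enamel; it is exposed in configuration
because it is poorly constrained.

Discretization uses exact fractional-overlap weights of each uniform
window on the grid (default step 0.1 mm), so kernels vary continuously
with geometry, sampled profiles converge under grid refinement (halving
the step moves predictions by < 0.01 ‰), and damping is monotone in
`lm` and `sample_length`. Rows of the averaging matrix are truncated at
the grid boundary and renormalized to sum to one — constant signals are
then reproduced exactly at the crown ends and no data is invented
beyond them.

## Inverse model

With the forward model linear (`d = A m`), recovery of the primary
signal on a fine grid is underdetermined. The estimate minimizes

    ‖A m − d‖² + ε² ‖D (m − m_ref)‖²

solved in closed form by Cholesky factorization of the normal equations.
`m_ref` is the data mean by default (a user vector is accepted). `D` is
selectable:

* `curvature` (default): scaled second differences, penalizing the
  integrated squared second derivative;
* `roughness`: scaled first differences;
* `reference`: the identity (classic damping toward `m_ref`).

The curvature default is a deliberate design choice. Zeroth-order
damping leaves a smooth wobble of several tenths of a permil in
otherwise exact reconstructions: the minimum-norm correction lives in
the span of the one-sided averaging kernels, and misassignment of the
~14 mm of input rootward of the last sample (which the data sense only
through kernel tails) aliases back into the sampled window. Its
noise-free round-trip floor is ≈ 0.6 ‰ interior RMSE regardless of
sampling density. The curvature penalty encodes the physically
motivated prior that the seasonal input is smooth at sub-millimetre
scales and reaches ≈ 0.12–0.17 ‰ on the same reconstructions, robustly
across growth phases and sample counts. The operators are scaled by
`step^-1/2` (roughness) and `step^-3/2` (curvature) so the penalty
approximates the continuous functional and ε keeps its meaning across
grid resolutions.

"Interior" nodes are those between the first and last sample centers;
estimates outside that window are reported but revert toward the prior.
For readable output and amplitude metrics, the estimate is averaged
over the drill width and evaluated at the sample positions
(`InversionResult.estimate_at_samples`); fine-grid extrema at window
edges are dominated by weakly constrained nodes and are not used for
amplitude.

### Damping selection and uncertainty

`choose_damping` applies the discrepancy principle: the largest
candidate ε whose residual RMS misfit is within the measurement-error
budget `sigma_meas` (preferring the smoothest solution consistent with
analytical error), falling back to the grid minimum with a warning.
Misfit is provably non-decreasing in ε, so the rule is well defined.
`sigma_meas` defaults to 0.3 ‰, the within-run repeatability of the
phosphate reference materials — a deliberately conservative figure.

`mc_error_bands` perturbs the data with Gaussian noise of sd
`sigma_meas`, re-inverts each trial at the same damping (one Cholesky
factorization, all trials solved together), and reports node-wise
2.5/97.5 percentiles. Bands are percentile rather than Gaussian because
the trial count is user-set; runs are bit-reproducible under a fixed
seed.

`invert_series` is the canonical pipeline and encodes a calibrated
two-scale choice. Damping is selected against
`DISCREPANCY_TAU × sigma_meas / √(mean replicate count)` — the standard
error of the triplicate means, scaled by a safety factor τ = 0.85 —
while the bands propagate the full per-measurement 0.3 ‰. The reasoning:
noise-propagation percentile bands carry no smoothing bias, so
discrepancy-maximal damping under-covers (≈ 87–88 % node-wise at a
nominal 95 %); the sub-unity τ limits the bias (the analytical σ is
itself an upper bound) and the conservative band scale widens the
bands. Both were calibrated by coverage simulation on synthetic teeth,
yielding ≈ 94 % empirical node-wise coverage without degrading
amplitude recovery. Users can reproduce either extreme by calling
`choose_damping`/`mc_error_bands` directly with their own σ.

`sensitivity_la` re-runs the inversion across candidate apposition
lengths (the least-constrained geometric parameter; reported values
span 2–12 mm) with everything else fixed.

## Seasonality metrics

Amplitude is max − min of the replicate means (per-tooth ranges are
read off mean profiles, not individual replicates). The percent of
annual range divides the enamel amplitude by the water amplitude after
conversion to phosphate space; comparing in water space instead differs
by exactly the calibration slope 0.9 and is available via
`space="water"`. Months recorded is `12 · span / growth_rate`.

## Cohort statistics

`fit_linear` is ordinary least squares with the slope standard error
and two-sided p for slope = 0; R² is the squared Pearson correlation. A
constant response returns slope 0 with R² defined as 0 (with a warning)
— degenerate but reachable in synthetic data; a constant predictor
raises. `welch_t` is the unequal-variance two-sided t test with
Satterthwaite degrees of freedom, chosen because the cohorts differ in
size and variance. `cohort_offsets` pools replicate means across each
cohort by default (per-specimen means via a flag), reports per-specimen
amplitudes, the between-cohort mean offset, and Welch tests on enamel
and (optionally) bone values.

## Synthetic data generator

The generator emulates a high-plains study system:

* **Water year** — cosine anchored exactly at the two printed monthly
  extremes (−23 ‰ January, −10.6 ‰ July); the pattern is described as
  sinusoidal and only those extremes are fixed. An optional seeded
  level perturbation (sd 1 ‰) emulates interannual variation.
* **Body water** — a seasonal mix of meteoric water and ¹⁸O-enriched
  leaf water. The summer leaf-water enrichment band (5–8 ‰) is
  field-constrained; the winter band (2–4 ‰) and the mixing fractions
  (0.7 winter, 0.3 summer — browsing shifts toward evergreen shrub
  leaves in winter) are assumptions, exposed in parameters. Band
  endpoints are drawn uniformly per individual when a generator is
  supplied, midpoints otherwise.
* **Teeth** — 10–14 samples at 2 mm spacing, triplicate measurements
  with 0.3 ‰ Gaussian noise. The growth phase starts at November ±
  0.5 months: births cluster tightly in early June and the third molar
  begins mineralizing around half a year of age. This matters — with a
  uniformly random phase, some 10-sample teeth (≈ 7 months of record)
  would genuinely miss a seasonal extreme, a sampling-window effect
  rather than an inversion failure.
* **Cohorts** — the historical cohort's input receives seasonal shifts
  (default +1 ‰ summer, −2 ‰ winter) before forward modeling. Bulk bone
  is a convex month-weighted mean of the input with March–August
  double-weighted (bone remodeling slows in winter) plus noise.

What the generator does *not* emulate: mechanistic leaf-water
evaporative enrichment (Craig–Gordon), migration between isotopic
regimes, body-water residence-time dynamics, wear truncation of the
occlusal record, diagenesis, and inter-laboratory calibration offsets.
Passing tests therefore show that the pipeline is internally consistent
under its own assumptions — they do not validate the physiological
model against real animals.

## Problem sizes in the test suite

The simulation-based checks use 20 seeded teeth for amplitude-recovery
properties, 200 teeth × 200 Monte-Carlo trials for band coverage, and
20 seeded cohort pairs (6 + 3 individuals) for the null comparison —
sizes at which the binomial/percentile criteria are stable while the
full suite completes in well under a minute of simulation time.

## Known limitations

* The drill-depth scaling of the apposition window is a geometric
  approximation; real appositional fronts curve.
* The forward model assumes a constant growth rate; real crowns
  decelerate toward the cervix.
* Truncate-and-renormalize at the crown ends biases edge samples toward
  the interior signal.
* The inversion reports no covariance between nodes; bands are
  node-wise only.
* Amplitude restoration above 100 % (observed on both real and
  synthetic teeth) reflects noise and deconvolution variance, not
  physical signal gain; it is bounded in practice by the discrepancy
  selection.
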