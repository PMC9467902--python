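# Methods

## The measurement problem

Hyperthermic intraperitoneal chemotherapy (HIPEC) circulates a heated
chemotherapy solution through the abdominal cavity after cytoreductive
surgery.  How much drug actually reaches the wall of the bladder, the
peritoneum, or 4 mm deep into the rectum is hard to measure: biopsies are
invasive, static, and report total rather than free drug.  Microdialysis
solves this by perfusing a semipermeable catheter at 1 µL/min and
collecting dialysate fractions continuously — but because the perfusate
never equilibrates with the tissue, each dialysate holds only a fraction
of the true free concentration.  That fraction, the relative recovery
(RR), differs per catheter and must be calibrated before dialysate
readings mean anything.

This package implements the full analysis chain for such a study —
calibration, correction, non-compartmental analysis (NCA), summaries and
between-compartment comparisons — together with a simulator that
generates complete synthetic studies with known ground truth, so every
stage is testable against closed-form answers.

## Calibration and correction

Retrodialysis-by-drug runs a known concentration `C_perfusate`
(100 µg/mL by default) through the catheter after the sampling period and
measures what is *lost* to the tissue:

    RR = 100 · (1 − C_dialysate / C_perfusate)        [percent]

Each catheter's RR is the mean of two 40-min retrodialysis samples.
Absolute free tissue concentrations then follow by inversion:

    C_tissue = 100 · C_dialysate / RR

Catheters with RR outside (0, 100] — e.g. dialysate ≥ perfusate, an
apparent negative recovery — are treated as malfunctioning and excluded
wholesale together with all their study samples; no substitution by a
compartment-mean RR is attempted, mirroring how whole-catheter losses are
handled in practice.  The exact numeric acceptance range is configurable
because no standard cut-off exists; (0, 100] is the defensible default
since RR is a fraction by definition.

Because a dialysate integrates drug over its whole collection window,
every concentration is timestamped at the midpoint of its sampling
interval (15, 45, …, 225, 270, 330, 390, 450 min under the default
30/60-min schedule).  Plasma is sampled by venous draws at those same
midpoints and passes through uncorrected — microdialysis and
ultrafiltration both report free drug, so the two compartments are
directly comparable.

Below-LOQ samples (LOQ = 0.100 µg/mL) are excluded from profiles but
counted, the conservative default when the original handling is unknown;
an LOQ/2 imputation policy (`loq_policy="halve"`) is provided for
sensitivity analysis.  Profiles never interpolate across lost samples.

## Non-compartmental analysis

Per animal × compartment profile:

* **Cmax / Tmax** — maximum observed concentration and its time; ties go
  to the earliest time (deterministic convention).
* **AUC_0-last** — linear up-log down trapezoid: rising or flat segments
  use `(C1+C2)Δt/2`, strictly falling segments use
  `(C1−C2)Δt/ln(C1/C2)`.  A falling segment that touches zero falls back
  to the linear rule (the log rule needs positive endpoints).  The curve
  is taken as zero at t = 0 — tissue contains no carboplatin before the
  perfusion starts — so the leading segment rises linearly from (0, 0)
  to the first midpoint; `leading_from_zero=False` switches this off for
  sensitivity analysis.
* **λz / T1/2** — ordinary least squares of ln(concentration) on time
  over a terminal tail of ≥3 points strictly after Tmax.  The default
  tail is the adjusted-R²-maximising suffix among the last k points
  (k = 3 … all post-Tmax points), requiring λz > 0; near-ties
  (ΔadjR² ≤ 1e-10) prefer the longer tail.  A fixed `last3` policy is
  available.  T1/2 = ln(2)/λz.  When no valid tail exists the result is
  flagged non-estimable rather than raised: with terminal half-lives of
  ~250–310 min under the default kinetics, the 8-h window simply does not
  contain two clean half-lives, and a missing T1/2 is the expected
  honest answer.

AUC extrapolation to infinity, clearance/volume estimation and
compartmental fitting are out of scope.

## Statistics

Per-compartment summaries are arithmetic means with two-sided 95%
t-intervals across animals (no CI when n < 2).  Between-compartment
comparison fits `value ~ compartment` with a per-animal random intercept
by REML (statsmodels MixedLM) and tests the compartment effect with a
Wald F statistic using residual denominator degrees of freedom
`N − k − (n_animals − 1)`, which reduces to the classical
repeated-measures `(n−1)(k−1)` in the balanced case.  This residual-df
approximation stands in for the Kenward–Roger small-sample correction,
which requires specialised machinery; consequently the overall p-values
are approximate with few animals, and the pairwise paired t-tests on
within-animal differences (complete pairs, exact df) are the primary
pairwise inference.  Pairwise p-values are unadjusted by default, with
optional Holm adjustment.  In the balanced two-compartment case the
mixed-model F equals the squared paired-t statistic with the same df, a
consistency that is tested.

## The simulator

Each compartment's true free concentration follows a Bateman-type
double-exponential

    C(t) = A · (exp(−k_elim·t) − exp(−k_uptake·t)),   k_uptake > k_elim > 0,

chosen over a mechanistic perfusate-depot ODE because it has closed-form
oracles — Tmax = ln(ku/ke)/(ku−ke), Cmax = C(Tmax),
AUC(0,T) = A[(1−e^(−ke·T))/ke − (1−e^(−ku·T))/ku], T1/2 = ln2/ke — and
still reproduces the key phenomenon of tissue peaks falling well after
the 90-min perfusion ends.  The equal-rate limit is rejected rather than
special-cased.  Default kinetics are calibrated per compartment by fixing
the rate ratio ku/ke = 4 (a moderate rise/decay separation) and solving
for (A, ke) so each population curve peaks exactly at the compartment's
literature Cmax/Tmax values (tissue Cmax 12.4–26.0 µg/mL, Tmax
175–206 min; plasma 10.6 µg/mL at 105 min).  The resulting terminal
concentrations at 450 min sit inside the observed 4.9–9.9 µg/mL band.

Observation layers, in order:

1. **Interval averaging** — an ideal dialysate measures the closed-form
   mean of C(t) over its window (verified against adaptive quadrature).
2. **Recovery loss** — per-catheter true RR is drawn from a
   per-compartment truncated normal on (0, 100] (redraw on violation)
   with means/SDs 75.2–93.1% (3.6–12.7 SD) matching the emulated study's
   calibration table.
3. **Assay noise** — multiplicative lognormal with unit mean; the CV is
   interpolated linearly in log10(concentration) between the five
   intermediate-precision points (20.8% at 0.100 µg/mL down to 3.5% at
   30 µg/mL, 6.8% at 100 µg/mL), clamped at the ends.  All measurement
   noise is attributed to the assay; no separate within-catheter residual
   term is simulated, as none is quantifiable from the source data.
4. **Censoring** — pre-censoring values below the LOQ are reported at
   the LOQ marker with the censored flag set, as an assay reports "<LOQ".
5. **Dropout** — whole catheters fail (malfunction or displacement) with
   configurable probabilities, defaulting to the observed 3/64 and 8/64
   rates; failed catheters contribute neither dialysates nor calibration
   samples.

All randomness flows through a single seeded generator recorded in
`SimTruth`, which also stores the kinetics, the per-catheter states and
the closed-form NCA truth (evaluated at the last scheduled midpoint,
450 min, the time of the last observation the pipeline can see), so any
dataset can be regenerated and audited exactly.

What the simulator does *not* emulate — and hence what passing tests do
not establish about real data: between-animal kinetic variability (all
animals share each compartment's truth curve, so per-animal scatter
comes only from recovery draws and assay noise and between-compartment
tests are far more powerful on synthetic data than in a real study,
where such differences were largely non-significant);
spatial heterogeneity and tumour tissue,
perfusate volume/temperature dynamics, drift or displacement that
partially corrupts a catheter instead of silencing it, model
misspecification (real tissue curves are not exact double exponentials),
and any within-catheter error beyond assay precision.  Tests demonstrate
that the pipeline's algebra and estimators are correct under the model,
not that the model is the truth.

## Numerical choices

* Full recovery (RR = 100%) is applied as an exact identity (no
  multiply-divide round trip), so the noise-free pathway reproduces the
  closed-form interval averages bit-for-bit and calibration→correction
  round trips are exact to ≤1e-12 relative.
* Tmax ties → earliest time; λz adjusted-R² near-ties → longer tail.
* The log trapezoid switches to linear when either endpoint is ≤ 0.
* Schedule construction requires steps to divide their spans exactly
  (1e-9 tolerance on the ratio); degenerate intervals are rejected.
* Empty profiles (all samples censored/excluded) carry a reason and are
  skipped by NCA, not fatal.
* Mixed-model convergence warnings on near-boundary variance components
  are suppressed; the Wald statistic is computed from the fixed-effect
  block of the REML covariance.

## Problem sizes

The stochastic verification suites use 200 replicates of the full
default study for AUC parameter recovery (median estimate/truth ratio
per compartment must lie in [0.9, 1.1]) and 500 parametric replicates
for the null calibration of the overall F-test (empirical type-I error
must lie in [0.01, 0.10] at α = 0.05).  Both are the package's chosen
verification sizes; the whole suite runs in under two minutes on one
CPU.
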