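# hipecmd

Tissue pharmacokinetics of carboplatin HIPEC from microdialysis data.

During hyperthermic intraperitoneal chemotherapy (HIPEC) a heated
carboplatin solution is circulated through the abdominal cavity, and the
clinically interesting question — how much free drug the peritoneum,
bladder wall, liver, mesentery or deeper rectal tissue actually sees,
and for how long — can be answered dynamically with microdialysis
catheters.  A dialysate, however, captures only a per-catheter fraction
of the true free concentration (the relative recovery, RR), pools drug
over its whole collection interval, and is censored below the assay's
limit of quantification.  `hipecmd` is the analysis pipeline for exactly
this kind of study, aimed at pharmacokineticists working with
(pre)clinical HIPEC or other microdialysis sampling designs:

* **study_design** — sampling schedules (30-min intervals over 0–240 min,
  60-min over 240–480 min by default; concentrations timestamped at
  interval midpoints), catheter ledgers and QC accounting;
* **dosing** — body-surface-area dosing via the porcine allometric
  formula `SA = 0.0970·W^0.633` and µM ↔ µg/mL conversions;
* **calibration** — per-catheter RR from retrodialysis-by-drug,
  `RR = 100·(1 − C_dialysate/C_perfusate)`, mean of two 40-min samples,
  with QC gating of physically impossible recoveries;
* **correction** — absolute free concentrations
  `C_tissue = 100·C_dialysate/RR`, LOQ policies, midpoint-timed profiles;
* **nca** — non-compartmental analysis: Cmax, Tmax, linear up-log down
  trapezoidal AUC_0-last (assumed zero at t = 0), λz by log-linear
  regression over an adjusted-R²-selected terminal tail, T1/2 = ln2/λz;
* **report** — per-compartment means with 95% t-intervals, a
  REML mixed model (compartment fixed, animal random) with overall F-test
  and pairwise paired t-tests;
* **simulate** — a synthetic-study generator whose double-exponential
  truth curves `C(t) = A(e^(−k_e t) − e^(−k_u t))` carry closed-form
  Cmax/Tmax/AUC/T1/2 oracles, layered with recovery loss, a
  concentration-dependent lognormal assay-noise ladder, LOQ censoring
  and whole-catheter dropout — so the entire pipeline is verifiable
  without any animal data.

See `docs/methods.md` for the model, its assumptions and its limits.

## Worked example

Simulate and analyse one full default study (8 pigs × 8 catheters × 12
dialysates plus plasma, assay noise and dropout on):

```python
import pandas as pd
from hipecmd import StudyConfig, run_study

result = run_study(StudyConfig(seed=1), out_dir="demo")
print(result.study.ledger.n_ok, "of", len(result.study.ledger.to_frame()), "catheters active")
print(pd.read_csv("demo/summary.csv")
        [["compartment", "n", "auc_mean", "cmax_mean", "tmax_mean"]].round(1))
```

```
53 of 64 catheters active
               compartment  n  auc_mean  cmax_mean  tmax_mean
              bladder_wall  6    8025.6       23.1      202.5
   hepatoduodenal_profound  7    4479.9       13.0      175.7
hepatoduodenal_superficial  5    5572.3       16.1      183.0
                     liver  7    4756.5       13.4      190.7
                 mesentery  6    4458.3       13.0      210.0
                peritoneum  8    9301.9       26.6      181.9
                    plasma  8    3092.0       11.0      120.0
           rectum_profound  7    7512.7       21.6      212.1
        rectum_superficial  7    5374.9       16.1      190.7
```

At this seed 11 catheters were lost to simulated malfunction or
displacement, so per-compartment n drops below 8 exactly as whole-catheter
QC exclusion dictates.  AUC_0-last is in min·µg/mL, Cmax in µg/mL and
Tmax in minutes: every tissue peaks 1–2 h *after* the 90-min perfusion
ends, plasma peaks earliest and lowest, and the peritoneum — in direct
contact with the perfusate — shows the highest exposure.  The run also
writes `doses.csv` (e.g. pig01 at 71.0 kg → 1.441 m² → 1,153 mg at
800 mg/m²), the raw `samples.csv`/`calibration.csv`, per-catheter
`recovery.csv`, corrected `profiles.csv`, per-animal `nca.csv`,
mixed-model `overall_tests.csv`/`comparisons.csv`, `mean_profiles.csv`,
and `truth.json` with the generating parameters and their closed-form
NCA values.  (Because all simulated animals share each compartment's
truth curve, compartment differences reach significance far more easily
than in real data — see `docs/methods.md`.)

The same pipeline runs from the shell, staged or end-to-end:

```bash
hipecmd run-all --seed 1 --out demo
hipecmd simulate --seed 1 --out demo   # then calibrate / correct / nca / report
```

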