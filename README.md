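# renalpbpk

Physiologically based pharmacokinetic (PBPK) simulation of renally cleared
drugs in virtual Chinese renal-impairment populations.

Dose adjustment of renally cleared antibacterials in patients with chronic
kidney disease (CKD) is often extrapolated from foreign data because
dedicated PK studies in impaired patients are hard to run. This package
provides the open building blocks for a model-based alternative, aimed at
clinical pharmacologists and PBPK modellers:

- **Virtual populations** of Chinese mild (GFR 60–89), moderate (30–59) and
  severe (15–29 mL/min/1.73 m²) renal-impairment patients, sampled from
  recalibrated covariate equations — per-sex height–age quadratics, an
  exponential weight–height relation BW = e^(a + b·BH), age-banded lognormal
  serum creatinine, hematocrit/AGP/HSA and CKD-stage kidney volume — with
  Cockcroft–Gault GFR, CLcr = (140 − Age)·BW/(72·Scr) (×0.85 female),
  enforced inside the category band by rejection sampling.
- A **whole-body perfusion-limited PBPK model** (12 tissues + arterial and
  venous blood) with mechanistic tissue:plasma partition coefficients
  (lipid/water or composition-based class-specific equations), a closed-form
  Kp scalar fitted so predicted Vss = V_p/BW + Σ Kp_t·V_t/BW matches the
  observed value, binding rescaled to subject HSA/AGP, and renal clearance
  scaled proportionally with GFR: CLr(subject) = CLr_ref · GFR/GFR_ref, with
  non-renal clearance held constant.
- **Virtual trials** (e.g. 10 trials × 10 subjects) with non-compartmental
  analysis: linear-up/log-down AUC, best-adjusted-R² terminal slope λz,
  AUC_inf = AUC_last + C_last/λz, Cmax, CL = Dose/AUC_inf, CLr.
- **Model qualification**: fold errors with inclusive 2-fold [0.5, 2] and
  1.25-fold [0.8, 1.25] windows, and
  MAPE(%) = (1/n)·Σ |pred_i − obs_i|·100/obs_i, compared across population
  models.

Parameter sets ship as YAML: three recalibrated Chinese CKD system models,
user-replaceable healthy placeholders, and four literature-informed drug
files (ceftazidime, cefodizime, vancomycin, cefuroxime). See
[docs/methods.md](docs/methods.md) for the model equations, assumptions and
limitations.

## Worked example

```python
from renalpbpk import DoseEvent, generate_population
from renalpbpk.io import load_drug, load_population
from renalpbpk.population import subjects_to_frame
from renalpbpk.trials import TrialDesign, run_trial, summarize_trials

mild = load_population("mild_cn")
cohort = subjects_to_frame(generate_population(mild, 4000, seed=1))
print(cohort.scr_umol_L.mean(), cohort.height.mean(), cohort.weight.mean())
# 107.2 µmol/L, 165.1 cm, 68.7 kg  — vs observed cohort means
# 109.31 µmol/L, 164.82 cm, 68.05 kg; every subject's normalised GFR
# lies in the mild band (here 60.0–89.0 mL/min/1.73 m²).

drug = load_drug("ceftazidime")
design = TrialDesign(mild, drug, [DoseEvent(1000, 0, 0.5)],
                     n_trials=10, n_per_trial=10)
_, pk = run_trial(design, seed=1)
print(summarize_trials(pk).loc["overall"])
# AUC_inf 221.5 ± 24.1 mg·h/L, Cmax 70.8 mg/L, CL 4.57 L/h, CLr 3.85 L/h
# for 1000 mg IV (0.5 h infusion): mild impairment roughly halves
# ceftazidime clearance relative to its healthy reference (6.9 L/h).
```

The same workflows are available from the shell:

```bash
renalpbpk genpop -p mild_cn -n 100 -s 1 -o subjects.csv
renalpbpk simulate -d ceftazidime -p severe_cn --dose-mg 1000 \
    --interval-h 24 --n-doses 10 -o out/
renalpbpk evaluate -r predictions.csv -o comparison.csv
renalpbpk fixtures -s 0 -o fixtures/   # drug files + synthetic observed PK
```

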