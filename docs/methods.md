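# Methods

## Scope and model overview

`renalpbpk` predicts intravenous pharmacokinetics of renally cleared drugs in
Chinese patients with chronic kidney disease (CKD) by coupling three models:

1. a **virtual population model** that samples demographic and physiological
   covariates of mild, moderate and severe renal-impairment patients from
   recalibrated covariate equations;
2. a **whole-body perfusion-limited PBPK model** (12 tissues + arterial and
   venous blood) with mechanistically predicted tissue:plasma partition
   coefficients and GFR-scaled renal clearance; and
3. **virtual trials** with non-compartmental analysis (NCA) and fold-error /
   MAPE model-qualification metrics.

Only IV dosing is supported; absorption, transporter kinetics, and CKD
effects on non-renal (hepatic) clearance are out of scope by design.

## Population model

Renal categories are defined on Cockcroft–Gault creatinine clearance
normalised to 1.73 m² body surface area (BSA): mild 60–89, moderate 30–59,
severe 15–29 mL/min/1.73 m². For each subject:

- **Age** is sampled uniformly over the category range (the observed age
  histograms are not available in tabulated form; an empirical distribution
  can be plugged in via `sample_age(..., age_dist=...)`).
- **Height** (cm) follows a per-sex quadratic in age,
  `BH = c0 + c1·Age + c2·Age²`, plus a Gaussian residual whose SD defaults to
  the observed per-sex cohort SD (e.g. 5.58 cm for mild males), truncated by
  resampling to 130–210 cm.
- **Weight** (kg) follows `BW = exp(a + b·BH_cm)`. The source table prints
  this relation inverted (as BH in terms of BW), which is dimensionally
  unusable (it would give BH ≈ 21 cm at BW 70 kg); the exponential
  weight-from-height reading reproduces the observed sex-specific mean
  weights within ~1–3% and is adopted as this package's interpretation.
- **Serum creatinine** (µmol/L) is lognormal within per-sex age bands,
  parameterised by the band's arithmetic mean and CV
  (σ² = ln(1+CV²), µ = ln(m) − σ²/2), guaranteeing positivity. Unit
  conversion uses 88.42 µmol/L per mg/dL.
- **GFR**: `CLcr = (140 − Age)·BW / (72·Scr[mg/dL])`, ×0.85 for females;
  normalised as `CLcr·1.73/BSA` with DuBois–DuBois BSA.
- **Band enforcement**: creatinine is rejection-sampled (≤100 draws) until
  the normalised GFR falls inside the category band; if exhausted, age (and
  the downstream covariates) are resampled (≤100 outer tries). This
  guarantees 100% containment while keeping the marginal covariate
  distributions close to their targets. A consequence worth knowing: near a
  band edge the truncation is asymmetric — in the moderate category the heavy
  upper creatinine tail is clipped at GFR = 30, which biases the cohort mean
  creatinine a few percent low relative to the untruncated band means.
- **Hematocrit and AGP** are lognormal (mean/CV per category and sex); **HSA**
  is a deterministic function of age. The HSA functional form is not public;
  the default `C0 + C1·Age + C2·(Age/10)²` gives physiologically plausible
  albumin (≈47 g/L at age 40, mild male) and is configurable (`hsa_form:
  quadratic` uses C2·Age² instead). The coefficients are carried verbatim
  from the parameter file.
- **Kidney volume** uses the linear form
  `V[mL] = baseline + bw_coeff·BW[kg] + bh_coeff·BH[m]` — the coefficient
  units are not stated in the source; this interpretation yields 239.6 mL
  (mild) and 118.8 mL (severe) at the observed cohort means, matching the
  expected monotone decline with CKD progression.
- **Reproducibility**: each subject draws from an independent child stream of
  the master seed keyed by subject index, so populations are byte-identical
  across runs and independent of generation order.

`derive_caucasian_mild` builds a Caucasian mild-RI model from a healthy model
by multiplying every creatinine band mean by 1.5 (the 60 vs 90
mL/min/1.73 m² cutoff ratio), leaving CVs and all other parameters unchanged;
a provenance flag guards accidental double application.

`validate_population` bins simulated subjects by age (10-year default) and
sex, computes 5th–95th percentile envelopes per covariate, and reports the
fraction of user-supplied observed points inside the envelope (≈0.90 expected
for data from the same generating process).

## Drug and partitioning model

Two standard Kp prediction schemes are implemented from tissue composition:

- **Lipid/water partitioning** (`poulin_theil`): neutral-species octanol:water
  P for non-adipose tissues, logD at plasma pH for adipose, with tissue
  unbound fraction approximated from the plasma one (interstitial protein at
  half plasma concentration).
- **Composition-based class-specific equations** (`rodgers_rowland`):
  Henderson–Hasselbalch ionisation at plasma (7.4), intracellular (7.0) and
  red-cell (7.22) pH; moderate-to-strong bases (pKa ≥ 7) bind acidic
  phospholipids with an association constant back-calculated from the
  blood:plasma ratio; acids, weak bases and zwitterions bind albumin and
  neutrals bind lipoproteins at the tissue:plasma protein ratio. Zwitterions
  take the acid branch on their acidic pKa.

The bundled composition table (`data/tissue_composition.yaml`) carries
literature-informed adult values in the style of the published composition
tables of this literature; the `rest` compartment uses an average soft-tissue
composition. Kp tests are deliberately limit- and property-based (water
partitioning limit, cross-method 2× agreement, positivity) rather than tied
to specific table entries.

**Vss** = (V_plasma + Σ_t Kp_t·V_t)/BW over the 12 model tissues. The **Kp
scalar** is fitted in closed form, s = (Vss_obs − Vp/BW)/(Vss_pred − Vp/BW),
since Vss is affine in a uniform scalar; the round-trip is exact to <1e−6.

**Binding**: fu is rescaled to the subject's HSA or AGP level assuming linear
binding, fu_s = 1/(1 + ((1−fu_ref)/fu_ref)·P_s/P_ref).

**Clearance**: the renal route scales proportionally with absolute
Cockcroft–Gault GFR against a configurable healthy reference of 120 mL/min;
the non-renal route is held constant across renal function (a stated
simplification — CKD effects on hepatic clearance and active renal transport
are not modelled). Drug files for vancomycin (≈25% tubular reabsorption) and
cefuroxime (≈28% active secretion) note this limitation explicitly.

## PBPK engine

Perfusion-limited mass balance per tissue with blood-referenced transport:
tissue venous outflow carries `C_t·BP/Kp_t`; gut and spleen drain into the
portal vein; the lung receives full cardiac output between venous and
arterial blood. Elimination follows the venous-equilibrium convention —
renal from the kidney at `CLr_int·C_kidney/Kp_kidney`, non-renal from the
liver analogously. Because venous-equilibrium elimination makes the apparent
systemic clearance smaller than the intrinsic organ term (well-stirred
extraction), the intrinsic clearances are back-calculated by inverting
`CL = CLint/(1 + CLint/(Q·BP))`; the model's Dose/AUC then equals the
prescribed systemic plasma clearance exactly, and a prescribed clearance
within 2% of the organ perfusion limit Q·BP is refused as unphysical.

Organ volumes scale linearly with body weight and flows with BSA from a
bundled 70-kg reference adult (cardiac output 336 L/h at BSA 1.8 m²); flow
fractions are renormalised to sum to one so flows conserve cardiac output by
construction. The kidney volume is overridden by the population model's
subject-specific value. Plasma concentration is reported as venous blood
concentration divided by the blood:plasma ratio.

Integration: piecewise `scipy.integrate.solve_ivp` (BDF) between dose-event
boundaries, rtol 1e−8 / atol 1e−10, default output grid 0.05 h; boluses jump
the venous state, infusions (default 0.5 h) add a constant venous input.
Mass balance |dosed − (in body + eliminated)|/dose is checked at every output
time against 1e−6 and observed at ~1e−10.

## Trials and NCA

A trial design is population × drug × regimen × sampling schedule (default
0.25–24 h post dose, typical for IV antibacterials; the clinical schedules
behind specific published studies must be supplied by the user). The
standard design is 10 trials × 10 subjects, generated as one 100-subject
population (the two groupings are equivalent because subjects depend only on
their index; verified by test).

NCA uses linear-up/log-down trapezoids; λz by unweighted log-linear
regression over terminal windows (≥3 points after Cmax) selected by maximum
adjusted R²; AUC_inf = AUC_last + Clast/λz; CL = Dose/AUC_inf. CLr is
computed as CL times the renal fraction of cumulative excretion at the end of
simulation — identical to Ae_renal(∞)/AUC_inf for this linear model in the
limit, and robust to truncation of slow terminal phases. Non-identifiable
terminal slopes (λz ≤ 0) flag the row and omit extrapolated quantities.

## Evaluation

`fold_error` classifies pred/obs into inclusive [0.5, 2] and [0.8, 1.25]
windows (inclusive reading of "within twofold"; both symmetric in log space).
`MAPE(%) = (1/n)·Σ|pred_i − obs_i|·100/obs_i`. `compare_models` ranks
population models by MAPE with the fold-window fractions alongside.

## Synthetic data and what passing tests show

The bundled drug files are literature-informed approximations (the original
study's supplementary input tables are not public), and the "observed" PK
fixture is generated by the simulator itself with lognormal CV-20% noise —
both are labelled as such in their files. Consequently the test suite
demonstrates (i) faithful recovery of the published population covariate
statistics, and (ii) internal correctness of the PBPK/NCA/evaluation
machinery against analytic oracles; it does not re-validate the published
clinical PK comparisons, which require the non-public observed datasets
(`evaluation` accepts user CSVs for that purpose). The healthy Chinese and
Caucasian population files are likewise user-replaceable placeholders for
proprietary system models.

## Problem sizes

Cohort statistics use 4,000 subjects per category (the published internal
validation size), generated in ~1 s each; trial simulations in the tests use
reduced designs (1–2 trials of a few subjects) chosen to exercise every code
path with seconds of compute, since the engine's per-subject cost is the
only thing larger designs add.

## Known limitations

- Uniform age sampling (observed histograms unavailable) shifts age-dependent
  covariates slightly relative to the observed cohorts.
- Band-edge rejection truncates creatinine tails asymmetrically (moderate
  category mean ≈6% low).
- Lumped GFR-proportional renal clearance ignores secretion/reabsorption;
  non-renal clearance is renal-function independent.
- Reference physiology and tissue composition are population-generic adult
  values; only kidney volume is Chinese-CKD specific.
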