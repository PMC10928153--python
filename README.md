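# wktau

**The central diastolic pressure decay time constant from routine pressure
features, on Windkessel virtual populations.**

## The problem

During diastole the aortic valve is closed and central blood pressure decays
approximately mono-exponentially.  Under the two-element Windkessel model —
the arterial tree lumped into a total compliance *C* (mL/mmHg) in parallel
with a total peripheral resistance *R* (mmHg·s/mL) —

```
C dP/dt = Q(t) − P/R
```

that decay has time constant **τ = R·C** (s), a compact marker of arterial
stiffness and vascular ageing.  Measuring τ directly requires the whole
central pressure waveform (tonometry, cycle averaging, an exponential fit).
This package studies a shortcut: combining the classical proportionality
C ∝ SV/cPP with R = MBP/CO and CO = SV/T gives

```
τ = k′ · T · MBP / cPP
```

with a single dimensionless coefficient k′, so τ follows from three routine
quantities — heart period *T*, mean pressure *MBP* and central pulse
pressure *cPP*.  In consistent units k′ equals the per-subject ratio
C·cPP/SV, which the Windkessel bounds above by 1 (the bolus-ejection
limit), and physiological ejection durations place near 0.6–0.8.

The package is written for hemodynamics researchers who want a fully
synthetic, ground-truth-exact testbed for this class of formula: every
virtual subject is a two-element Windkessel with *known* τ = R·C, solved in
closed form, so estimator error is attributable to the estimator alone.

## What is inside

| module | role |
| --- | --- |
| `wktau.windkessel` | exact periodic solution of the WK2 ODE under half-sine or triangular ejection flow |
| `wktau.population` | seeded virtual cohorts (truncated-normal R, C, T, SV; Weissler-type ejection duration), measurement noise, brachial PP surrogate |
| `wktau.features` | SBP/DBP/MBP/cPP extraction, clinical MBP formulas, Savitzky–Golay smoothing, beat averaging, cuff calibration |
| `wktau.tau` | τ estimators: reference R·C, diastolic decay fit, the k′ formula, pulse-pressure-method compliance |
| `wktau.fitting` | origin-constrained recovery of k′; HR/MBP tertile, age, gender and MBP-formula sensitivity fits |
| `wktau.agreement` | Pearson r, ICC(2,1), Wald-tested regression, nRMSE, Bland–Altman |
| `wktau.pipeline`, `wktau.cli` | derive-then-evaluate orchestration, CSV/YAML I/O, `wktau` command |

The numbered scripts under `analysis/` run the study end to end and write
their tables under `results/`.

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/02_extract_features.py
python analysis/04_fit_coefficient.py
```

prints, among other output:

```
simulated n=3818 subjects (seed=1) -> results/cohort_truth.csv
parameter     mean      sd   target mean
R            0.999   0.199          1.00
C            1.173   0.445          1.10
T_s          0.701   0.098          0.70
...
pooled origin fit (n=3818): k' = 0.645, R^2 = 0.993

HR / MBP tertile fits:
variable   group    n  kprime    R2
      HR     <Q1 1273   0.666 0.997
      HR [Q1,Q3] 1272   0.645 0.997
      HR     >Q3 1273   0.627 0.996
...
brachial refit (bPP = 1.267 * cPP): k' = 0.817 = 1.267 * pooled k' (exact rescaling)
```

Reading: on 3818 virtual subjects the origin-constrained fit of τ = R·C
against T·MBP/cPP recovers k′ = 0.645 with R² = 0.99; the coefficient drifts
only weakly across heart-rate tertiles (0.666 → 0.627, low to high HR,
driven by the rising ejected fraction of the cycle at faster rates); and
replacing central with brachial pulse pressure (amplification 57/45)
rescales k′ exactly to 0.817.  `analysis/05_evaluate_agreement.py` then
scores the fixed-coefficient formula on a held-out noisy cohort with the
full agreement battery (scatter and Bland–Altman figure included).

The same machinery is scriptable:

```python
from wktau import PopulationConfig, cohort_with_features, fit_kprime, predictor

cohort, subjects = cohort_with_features(PopulationConfig(n=500, seed=7))
fit = fit_kprime(cohort["tau_true"], predictor(cohort))
print(fit.kprime, fit.R2)
```

or via the CLI: `wktau generate`, `wktau fit`, `wktau evaluate`,
`wktau run-all`, `wktau reproduce-tables`.

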