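# Methods

## Model

Each virtual subject is a two-element Windkessel: total arterial compliance
C in parallel with total peripheral resistance R, driven by a parametric
ejection flow Q(t) over one heart period T,

    C dP/dt = Q(t) − P/R.

The periodic steady state is computed in closed form.  The ODE is linear,
so the zero-initial-state response p₀(t) determines the periodic solution
through P(t) = p₀(t) + P(0)·e^(−t/τ) with P(0) = p₀(T)/(1 − e^(−T/τ)).
Consequences used throughout:

- the diastolic limb equals P(ts)·e^(−(t−ts)/τ) exactly, with τ = R·C, so
  the decay-fit estimator has an unambiguous ground truth;
- the time-average pressure equals R·SV/T exactly (flow in equals leak
  out), so MBP, cardiac output and R are mutually consistent;
- C·PP/SV ≤ 1 for every parameter set, with equality in the instantaneous-
  ejection (bolus) limit.  This ratio is exactly the dimensionless
  coefficient k′ of the formula τ = k′·T·MBP/cPP, since R = MBP·T/SV makes
  τ = (C·cPP/SV)·(T·MBP/cPP) an algebraic identity per subject.

Two ejection profiles are provided, half-sine (default) and triangular;
both admit analytic solutions, and comparing them bounds the shape
sensitivity of k′.  Sampling grids use dt = T/round(fs·T) so one period is
tiled exactly (the effective rate differs from the requested fs, default
1000 Hz, by < 0.1%); without this the sample-mean MBP picks up an
O(1/(fs·T)) error that dominates the exactness budget of the resistance
and compliance estimators.

## Virtual population

Parameters are drawn independently per subject from truncated normals
(uniform for fractions), seeded and bit-reproducible:

| parameter | distribution | bounds | rationale |
| --- | --- | --- | --- |
| R (mmHg·s/mL) | N(1.0, 0.2) | [0.4, 1.8] | healthy-adult total peripheral resistance |
| C (mL/mmHg) | N(1.1, 0.5) | [0.3, 3.0] | healthy-adult total arterial compliance |
| T (s) | N(0.7, 0.1) | [0.45, 1.1] | resting heart periods ~55–130 bpm |
| SV (mL) | N(70, 14) | [35, 120] | cardiac output ≈ 6 ± 1.2 L/min at T = 0.7 s |
| age (y) | U(35, 55), gender 50/50 | — | middle-aged screening-cohort demographics |

Ejection duration defaults to a Weissler-type systolic-time-interval
relation, ts = 0.413 − 0.0017·HR seconds plus N(0, 0.01 s) subject jitter,
clipped to [0.20, 0.45]·T.  Absolute ejection time varies far less than the
heart period, so the ejected fraction ts/T rises with heart rate (≈ 0.29 at
55 bpm to ≈ 0.45 at 130 bpm, cohort mean 0.38).  This coupling matters:
k′ = C·cPP/SV depends mainly on ts/T (decreasing) and only weakly on τ/T,
so the LVET relation is what gives the fitted coefficient its weak negative
heart-rate trend (tertile fits 0.666/0.645/0.627).  An independent
uniform(0.30, 0.40) ts/T mode is available (`ejection.mode="fraction"`);
under it the trend flattens and loses its direction.  Resulting cohort
pressure moments: SBP 126 ± 38, DBP 80 ± 32, cPP 45.7 ± 24, MBP 102 ± 33
mmHg — central pulse pressure centred on the mid-40s as intended, with a
somewhat heavier spread than real screening cohorts show.

What the generator does **not** emulate: wave propagation and reflection
(no arterial geometry), pressure-dependent compliance, ventricular–arterial
coupling, and R–C correlation (draws are independent, so the cohort mean of
τ = R·C coincides with the product of means, unlike in vivo populations
where R and C are negatively correlated).  Passing tests therefore
demonstrate correctness of the estimators and fitting machinery on
Windkessel ground truth, not performance on reflected, distributed-tree
waveforms.

An optional measurement layer emulates tonometry acquisition: the clean
cycle is tiled to ~20 s with multiplicative beat-length jitter, white
sensor noise and a linear baseline drift are added, and cuff calibration
anchors (DBP, MBP) carry Gaussian error.  Evaluation defaults: jitter 2% of
T, white noise 1 mmHg, drift 3 mmHg per recording, 2 mmHg on both anchors.
A scalar brachial surrogate maps bPP = a·cPP with a ~ N(57/45, 0.05),
mimicking central-to-peripheral pulse-pressure amplification.

## Estimators

- **Reference**: τ = R·C from the generator (exact by construction).
- **Decay fit**: log-linear least squares of log P on t over the diastolic
  window, which starts 5% of T after ejection end (skipping the incisura
  region) and runs to end-cycle; nonlinear least squares is available for
  windows containing non-positive samples.  On clean data both agree with
  R·C to round-off.
- **Formula**: τ = k′·T·MBP/cPP with MBP defaulting to the waveform
  integral mean; five clinical MBP approximations (0.42·SBP + 0.58·DBP,
  DBP + 0.33·PP, DBP + 0.33·PP + 5, the heart-rate-adjusted form factor,
  and √(SBP·DBP)) feed the sensitivity analysis.  Note the +5 mmHg variant
  does not coincide with the others in the degenerate PP → 0 limit — it
  keeps its additive offset.
- **Pulse pressure method**: the compliance for which a Windkessel driven
  by the subject's flow reproduces the measured pulse pressure.  Predicted
  PP decreases strictly in C, so the match is a bracketed Brent root find
  (|ΔPP| < 1e−8 mmHg); an optional mode truncates the flow to its first
  five harmonics (the classical low-frequency variant) before solving
  spectrally.

## Coefficient fitting and evaluation

k′ is recovered by least squares through the origin, k′ = Σxτ/Σx² with
x = T·MBP/cPP — the formula has no intercept, and the slope equals the
x²-weighted mean of the per-subject ratios τ/x.  R² is reported against the
centred total sum of squares so values are comparable with ordinary
regression (an uncentred option exists; an OLS-with-intercept fit is kept
for comparison).  Subgroup fits use sorted equal-third tertiles for HR and
MBP (outer groups take the remainder: 3818 → 1273/1272/1273), age bins
<40 / 40–50 / >50, and gender.

The agreement battery reports Pearson r; ICC(2,1) — two-way random
effects, absolute agreement, single measures, chosen because the question
is agreement between methods, not mere consistency — from explicit ANOVA
mean squares; OLS of estimate on reference with a two-sided Wald t-test of
the slope (n − 2 df); RMSE normalised by the reference range; and
Bland–Altman bias with 1.96·SD limits of agreement (sample SD, ddof = 1).

Cycle processing: beat feet are detected as pressure minima on the linearly
detrended recording with a minimum spacing of 70% of the autocorrelation
period; each cycle is linearly detrended so its endpoints coincide,
resampled to the median cycle length, and averaged; Savitzky–Golay
smoothing (window 51 samples at 1 kHz, order 3) is optional.  The averaged
cycle starts at the foot; in the Windkessel the pressure minimum falls a
few milliseconds after ejection onset (dP/dt < 0 until Q exceeds P/R), a
pure phase offset that does not affect any extracted feature.

## Problem sizes and reproducibility

The derivation cohort is n = 3818 with seed 1; the held-out evaluation
cohort is n = 2263 with a distinct seed and the measurement layer enabled.
Property and Monte-Carlo tests use 20–1200 subjects and up to 1000 noise
replicates.  All randomness flows from explicit integer seeds through
`numpy.random.Generator`; rerunning any stage with the same configuration
reproduces every CSV cell bit-identically.  `scripts/acceptance.py
--seed S --out F` regenerates the cohort and refits from scratch.

## Known limitations

- Without wave reflections the per-subject identity τ = (C·cPP/SV)·x makes
  the fit far tighter than distributed-model data: R² ≈ 0.99 here, whereas
  reflected waveforms decouple cPP from C·SV and widen the scatter.  The
  fitted k′ level (≈ 0.64) and all subgroup *directions* are informative;
  the R² is a property of the stand-in generator, not of the formula.
- The independent C draw produces a minority of subjects with very small
  pulse pressure (cPP below ~15 mmHg at high compliance).  Under cuff
  calibration error these subjects dominate the evaluation tails — the
  formula divides by cPP — which is the main driver of the held-out
  limits of agreement.  Real screening cohorts do not contain such
  subjects, so the noisy-evaluation figures are conservative.
- The brachial surrogate is a scalar amplification; no peripheral waveform
  morphology is modelled.
- Decay-window placement assumes the ejection duration is known (true for
  synthetic subjects); applying the decay fit to measured waves would need
  an ejection-end detector, which is out of scope.
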