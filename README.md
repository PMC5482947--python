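# sivar

Model-based insulin sensitivity (SI), its hour-to-hour variability (%ΔSI),
and bootstrap difference/equivalence testing between outcome groups in
glycaemic-control (GC) cohorts.

`sivar` is aimed at researchers in critical-care metabolism who want to ask
whether two patient groups (e.g. ICU survivors vs non-survivors) differ in
metabolic *level* or metabolic *variability* — and whether any difference is
clinically meaningful given blood-glucose (BG) measurement error. Because
real ICU datasets are rarely shareable, the package ships a synthetic
virtual-patient generator so that every stage of the pipeline is testable
end-to-end on known ground truth.

## The model and the statistics

Glucose–insulin kinetics follow a three-compartment ICING-type model
(blood glucose G mmol/L, plasma insulin I mU/L, interstitial insulin Q mU/L):

```
dG/dt = −p_G·G − SI·G·Q/(1 + α_G·Q) + (P(t) + EGP − CNS)/V_G
dI/dt = −n_K·I − n_L·I/(1 + α_I·I) − n_I·(I − Q) + u_ex(t)/V_I + (1 − x_L)·u_en(G)/V_I
dQ/dt =  n_I·(I − Q) − n_C·Q/(1 + α_G·Q)
```

with exogenous insulin `u_ex` and carbohydrate-derived glucose appearance `P`
piecewise constant. SI (L/mU/min) is the patient-specific, hour-to-hour
time-varying parameter.

**Hourly SI identification.** The I/Q subsystem is SI-free, so it is
simulated once from the recorded insulin schedule (with endogenous secretion
evaluated on interpolated BG); integrating the glucose equation over each
hour then gives SI in closed form:

```
SI_h = [ −ΔG_h − p_G·∫G dt + ∫(P + EGP − CNS)/V_G dt ] / ∫ G·Q/(1 + α_G·Q) dt
```

**Variability.** `%ΔSI_i = 100 × (SI_{i+1} − SI_i)/SI_i`, the forward
hour-to-hour percent change.

**Statistics.** SI and %ΔSI are pooled into 6-h blocks per outcome group
over the first 72 h of therapy. Each block is compared by (i) a percentile
bootstrap (1000 resamples) of the difference of medians, read at 95% and at
the Bonferroni-consistent 99.6% level (0.05/12 ≈ 0.004 for twelve blocks),
(ii) a two-sample Kolmogorov–Smirnov test, and (iii) an equivalence test:
the groups are clinically equivalent in a block when the 95% CI of their
difference lies wholly inside the equivalence range derived from BG
measurement error (SD 9.4%) — about ±12–17% depending on BG, ≈ ±14% at
mid-band. Difference and equivalence are independent verdicts: a difference
can be statistically significant yet clinically equivalent.

## Worked example

```python
from sivar import CohortAnalysis, CohortConfig, InsulinSensitivityModel, generate_cohort

cfg = CohortConfig(n_survivors=30, n_nonsurvivors=10, seed=42)
cohort = generate_cohort(cfg)                      # closed-loop virtual patients
results = CohortAnalysis(cohort.records, seed=42).fit()
print(results.summary())
```

prints

```
Cohort comparison of insulin sensitivity and its variability
==============================================================

cohort1: 39 included, 1 excluded
  SI level : equivalent in 0/12 blocks, significant (95%) in 3, after Bonferroni in 2
  %dSI     : equivalent in 7/12 blocks, significant (95%) in 1, after Bonferroni in 0
  cohort BG: +5.6% [-0.5, +10.0] vs +/-9.4% -> not equivalent

cohort2: 29 included, 11 excluded
  SI level : equivalent in 0/12 blocks, significant (95%) in 5, after Bonferroni in 4
  %dSI     : equivalent in 6/12 blocks, significant (95%) in 1, after Bonferroni in 0
  cohort BG: +9.5% [+4.7, +15.0] vs +/-9.4% -> not equivalent
```

The generator gives non-survivors a 20% higher SI level with identical
hour-to-hour variability, and the analysis reads that structure back: SI
level is never equivalent, while %ΔSI is mostly equivalent even in this
small 40-patient cohort (at study-size cohorts of ~145 patients the %ΔSI
CIs tighten and all twelve blocks come back equivalent). `cohort1` requires
therapy start within 12 h of admission plus ≥24 h of data; `cohort2` is the
≥72 h subset that controls for dropout.

Per-patient fits are ordinary model objects:

```python
res = InsulinSensitivityModel(cohort.records[0]).fit(72)
print(res.summary())
```

```
Insulin Sensitivity Profile
===========================
patient:        S001
hours fitted:   72
flag counts:    ok=72, clamped=0
SI median [IQR]: 3.864e-04 [2.349e-04, 6.834e-04] L/mU/min
%dSI median [IQR]: +3.4 [-6.4, +20.5] %
```

A CLI wraps the same pipeline: `sivar simulate`, `sivar identify`,
`sivar analyse`, `sivar report` (see `sivar --help`).

## Layout

| module                 | contents                                              |
|------------------------|-------------------------------------------------------|
| `sivar.icing`          | model parameters, ODE right-hand side, simulation     |
| `sivar.records`        | patient records and their CSV dialect                 |
| `sivar.identification` | integral-method hourly SI fitting (model/results)     |
| `sivar.variability`    | %ΔSI, 6-h block pooling, empirical CDFs               |
| `sivar.equivalence`    | bootstrap CIs, KS test, equivalence ranges/verdicts   |
| `sivar.cohort`         | virtual-patient cohort generator and controller       |
| `sivar.analysis`       | cohort selection and the end-to-end comparison        |
| `sivar.cli`            | command-line interface                                |

See `docs/methods.md` for modelling assumptions, parameter provenance,
numerical choices and known limitations.
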