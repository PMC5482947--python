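# Methods

This note records the modelling assumptions, parameter provenance, numerical
choices and known limitations of `sivar`. It states no empirical result that
the test-suite or `scripts/acceptance.py` does not itself compute.

## 1. Glucose–insulin model

The three-compartment ICING-type model tracks blood glucose G (mmol/L),
plasma insulin I (mU/L) and interstitial insulin Q (mU/L). Insulin acts on
glucose through the saturating term `SI·G·Q/(1+α_G·Q)`; insulin kinetics
include renal clearance (n_K), saturable hepatic clearance (n_L, α_I),
plasma↔interstitium exchange (n_I) and interstitial degradation (n_C);
first-pass hepatic extraction removes a fraction x_L of endogenous
secretion. Constant endogenous glucose production (EGP) and CNS uptake are
lumped source/sink terms.

Default constants (in `sivar/_defaults/icing_params.json`, version 1) are
literature-standard values for critically ill adults: p_G = 0.006 min⁻¹,
α_G = 1/65 L/mU, α_I = 0.0017 L/mU, n_K = 0.0542 min⁻¹, n_L = 0.1578 min⁻¹,
n_I = n_C = 0.006 min⁻¹, x_L = 0.67, V_G = 13.3 L, V_I = 4.0 L,
EGP = 1.16 mmol/min, CNS = 0.3 mmol/min. No default is hard-coded in
computation; everything flows through `IcingParameters`.

Two deliberate conventions:

* **Renal clearance sign.** All insulin clearance terms act as losses on I.
  A `printed_nk_sign` audit flag restores the alternative (+n_K·I) sign that
  appears in some printed versions of the equations; with that sign plasma
  insulin is not mass-conservative, so the clearance form is the default.
* **Endogenous secretion.** u_en(G) is a bounded, non-decreasing saturating
  linear function, `clip(14.9·G − 49.9, 16.7, 266.7)` mU/min, selected
  because secretion enters the model as a function of G and must be bounded;
  `u_en_active=False` models C-peptide-suppressed patients. Exact published
  secretion sub-models vary; the form here is configurable and the
  identification is insensitive to it at typical exogenous infusion rates
  (endogenous input is ~20% of the insulin source at 3 U/h and G ≈ 6).

**Integration.** `simulate` uses an adaptive stiff-capable integrator
(LSODA by default, rtol 1e-6 / atol 1e-8) and restarts at every SI or input
discontinuity so piecewise-constant steps are honoured exactly. Tolerances
were chosen so identification error is dominated by data, not integration;
the test-suite checks agreement with a 0.005-min explicit-Euler oracle to
better than 1e-4 relative. Times are minutes; hour indices are 0-based,
half-open [h, h+1).

## 2. Hourly SI identification (integral method)

Because the I/Q equations are SI-free, they are simulated once per record —
driven by the recorded insulin schedule and by u_en evaluated on
*interpolated* BG, which keeps the subsequent solve linear — and the glucose
equation is integrated over each hour, giving the closed form

SI_h = [ −ΔG_h − p_G·∫G + ∫(P+EGP−CNS)/V_G ] / ∫ G·Q/(1+α_G·Q).

Numerical conventions (fixed for reproducibility; no canonical published
choice exists):

* BG is interpolated piecewise-linearly; integrals are composite trapezoids
  on a 1-min grid; ΔG_h uses the interpolated values at the hour boundaries
  (exact at measurement times).
* The I/Q subsystem is integrated with fixed-step RK4 at 0.5-min substeps
  (checked against a fine Euler oracle to <1e-4 relative).
* Initial I/Q at therapy start are the endogenous-secretion-only equilibrium
  for the first measured BG — the same convention the generator uses — since
  exogenous insulin starts with therapy. The I time constant is minutes and
  Q tens of minutes, so this choice only matters in the first hours.
* Hours are therapy-start-anchored. Hours only partially covered by BG data
  (record edges) are dropped, never extrapolated.
* A negative solution (possible under measurement noise) is clamped to
  si_min = 1e-8 L/mU/min and flagged `clamped`, keeping downstream %ΔSI
  finite; SI is physiologically non-negative. An hour whose insulin-exposure
  integral is below 1e-6 (no insulin in plasma at all) carries no SI
  information and is flagged `unidentifiable`, with no value emitted.

Accuracy, measured by the suite on synthetic truth: with noise-free hourly
BG the median absolute relative error is ≈0.6%; with 5-min BG <1%; under
9.4% multiplicative BG error the identified SI is median-unbiased (sign
test) with a per-hour error spread of roughly ±15–20%.

## 3. Variability metric and pooling

%ΔSI_i = 100·(SI_{i+1} − SI_i)/SI_i, the forward difference; it exists only
where both hours were identified and SI_i > 0. A %ΔSI value at hour i is
assigned to the 6-h block containing i (so block b covers transitions
starting in [6b, 6b+6)); the final block has six values when hour 72 was
identified, else five. Values touching a clamped hour are retained in the
distributions but flagged `from_clamped` for sensitivity analysis. Pooling
is across patients and hours, per outcome group, in deterministic
(patient_id, hour) order; empirical CDFs are right-continuous steps.

## 4. Difference and equivalence testing

* **Bootstrap.** Percentile bootstrap (simplest defensible choice; BCa was
  rejected as an unnecessary additional assumption), 1000 resamples with
  replacement at the original sizes, of the difference of medians. CIs at
  95% and 99.6% — the latter consistent with a Bonferroni-corrected
  per-test level of 0.05/12 ≈ 0.004 for the twelve-block family. The SI
  comparison is emitted both as an absolute difference (reporting form) and
  as a percent of the non-survivor median (equivalence form, computed from
  the same resampling stream); %ΔSI differences are already in percent
  units. Seeding is hierarchical: one analysis seed spawns fixed
  per-(cohort, metric, block) substreams, so adding a block never perturbs
  the others and reruns are byte-identical.
* **KS test.** Two-sided two-sample Kolmogorov–Smirnov; exact null
  distribution for small samples, asymptotic at study scale.
* **Equivalence.** A block is equivalent when the 95% CI lies wholly inside
  ±half-width. Equivalence and significance are independent verdicts.

### Measurement-error equivalence range

The half-width answers: *how large a relative change in identified SI can a
1-SD BG measurement error produce?* Changes smaller than that are
indistinguishable from meter error. The implementation scales the fitting
window's BG by (1 ± sd) — a systematic meter calibration error — re-runs the
same integral identification, and averages the two perturbation magnitudes
(symmetric first-order sensitivity). At a steady reference with suppressed
secretion this sensitivity has the closed form ε / (1 − p_G·G·V_G / (P +
EGP − CNS)): it is independent of SI and insulin dosing, widens with BG and
narrows with carbohydrate rate. Following the stringency principle — the
*narrowest* range over the span of clinical inputs actually observed under
protocolised GC — the reported half-width at each BG is the minimum over a
carbohydrate grid of 2–6 g/h with secretion active and suppressed. With
sd = 9.4% this yields ≈12.6% at BG 4.4, ≈14.3% at BG 6 and ≈17.3% at BG 8.
The per-block range is evaluated at the block's pooled median BG. The exact
arithmetic behind historically reported ranges is not public; this
derivation is the package's own, stated approximation.

The cohort-level BG check uses ±9.4% (1 SD of meter error) directly on the
percent difference of pooled median BG.

## 5. Synthetic cohort generator

The generator emulates the statistical structure of a protocolised ICU GC
cohort; it is not a fit to patient data.

* **True SI**: geometric random walk on log-SI. Hourly step SD interpolates
  0.30 → 0.10 over 72 h (variability decreases as control progresses),
  deterministic drift ×1.3/day (SI recovers over the first days), survivor
  baseline median 1.5e-4 L/mU/min with a 0.40 log-SD patient-level spread,
  non-survivors ×1.2 (the observed "≈20% higher" level with *identical*
  variability). Trajectories are truncated to [1e-6, 5e-3]. Lognormal
  dynamics guarantee positivity and the right-skewed pooled distributions
  seen in such cohorts.
* **Control loop**: a stylized table-like protocol (stand-in for the
  unpublished clinical look-up tables) acts at each measurement: insulin
  rises in 1 U/h steps with hyperglycaemia or a rising trend in the upper
  band, capped at 6 U/h, cut on hypoglycaemia; feed is reduced in 10% steps
  of a 4 g/h goal under persistent hyperglycaemia (floor 30%) and restored
  in band. Target band 4.4–8.0 mmol/L.
* **Measurement**: BG every 90 min (~16/day), multiplicative Gaussian error
  SD 9.4% truncated at ±3 SD (glucometer CV interpretation); the controller
  sees the *noisy* values.
* **Dropout**: lognormal length of stay (median 120 h, log-SD 0.9, floor
  12 h) truncates records, creating the ≥24 h vs ≥72 h cohort structure;
  therapy starts uniformly within 12 h of admission. LOS is sampled
  independently of SI level (the true joint structure is unknowable without
  patient data; couple them via configuration if desired).

What the generator does **not** emulate: nutrition composition and enteral
absorption dynamics, drug effects on SI (steroids, β-blockers,
hypothermia), renal replacement, diurnal rhythm, bolus-timing jitter, or
any SI–LOS competing-risk coupling. Passing tests therefore demonstrate
that the *pipeline* recovers known structure under realistic noise and
dropout — not that real cohorts have that structure. One visible artefact:
with resistant virtual survivors against a 6 U/h insulin cap, the synthetic
between-group BG gap (and cohort insulin use) runs somewhat higher than
real protocolised cohorts report.

## 6. Statistical calibration and its limits

Under a null configuration (multiplier 1.0, shared variability, 25+25
patients, ten seeds) the %ΔSI block bootstrap excludes zero in ≈5% of
blocks and the KS p-values are uniform — %ΔSI values are increments of the
log-SI walk and essentially serially independent, so iid resampling is
honest for them. Pooled SI *levels*, by contrast, are strongly
within-patient correlated (a random walk keeps a patient high or low for
many consecutive hours), so an iid bootstrap of pooled hourly levels
understates the sampling variance of the block median and its CIs are
anti-conservative as group-difference inference. This is a property of the
pooled-level design itself, shared by any analysis that resamples pooled
hourly values; SI-level significance flags should be read with that caveat
(the equivalence verdicts, which compare CI location against a fixed
clinical band, are less affected).

## 7. Problem sizes and determinism

The suite and the acceptance script use: 100 virtual patients (50+50,
noise-free, hourly BG) for recovery accuracy; ten 25+25 null cohorts for
calibration; one 119+26 study-structure cohort for the qualitative
between-group result; 500-rep Monte-Carlo coverage checks at n = 200 per
arm. These sizes make all Monte-Carlo bands comfortably wide while keeping
a full run in minutes on one CPU. All randomness flows from explicit seeds
(cohort seeds spawn per-patient child streams; analysis seeds spawn
per-block substreams); reruns with the same seed are byte-identical.

## 8. Known limitations

* Only SI is identified; all other constants are population defaults, so
  identified SI absorbs their patient-level misspecification. This matches
  the method's intent (a practical hourly sensitivity marker, cross-validated
  elsewhere against clamp measures) but SI values should be compared across
  groups, not read as clamp-grade measurements.
* One-hour identification windows are fixed; no overlapping-window or
  stochastic-filtering variants.
* The equivalence range is a first-order, steady-reference approximation and
  is reported per block at the pooled median BG, not per patient.
* The stylized controller is not any published table protocol; only its
  qualitative feedback structure (insulin *and* feed modulation toward a
  4.4–8.0 band) is representative.
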