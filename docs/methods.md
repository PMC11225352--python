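# Methods

This note documents the models, estimators and simulation conditions
implemented in `silkstudy`, the choices made where the design was genuinely
open, and what the synthetic-data experiments do and do not demonstrate.

## 1. The measurement setting

Stable Isotope Labeling Kinetics (SILK): subjects receive a primed
intravenous ¹³C₆-leucine infusion (3 mg/kg bolus, then 2 mg/kg/h for the
remainder of 9 h) and serial lumbar CSF sampling through an indwelling
catheter — 6 mL every 2 h for 36 h (19 draws). Immunoprecipitation mass
spectrometry yields, per draw, the labeled mole fraction of Aβ38/Aβ40/Aβ42
(tracer/(tracer+tracee)) and the Aβ concentration. Plasma leucine
enrichment is measured on the same schedule.

## 2. Aβ40 transport model

Five well-mixed compartments carry soluble Aβ40: brain interstitial fluid
(ISF, volume `V_ISF` = 250 mL), the ventricles, the cisternal, cranial and
spinal subarachnoid space (SAS). State is concentration (nmol/mL) of the
labeled and unlabeled species; the system is linear and time-invariant for
a fixed parameter set.

Processes and rates:

* **Production.** Aβ40 enters the ISF at `f_ab40 · R_APP` nmol/h
  (`f_ab40` = 0.1, the stoichiometric yield of Aβ40 per APP). The labeled
  share at time *t* is `p(t) = 1 − (1 − e(t − τ))^n_leu`, where `e(·)` is
  plasma leucine enrichment, `τ` = 3 h is a lumped synthesis/processing
  delay, and `n_leu` = 1 by default so the simulated labeled fraction is
  directly the precursor-normalized quantity FSR assumes. `n_leu` = 2 is
  available for realism experiments.
* **ISF clearance.** First-order loss `k_BPD40 · C_ISF` lumping proteolytic
  degradation and blood–brain-barrier efflux; admissible range
  0.05–0.35 /h.
* **ISF → ventricular transport.** Equivalent flow `k_t (C_ISF − C_V)`,
  `k_t` = 15 mL/h.
* **Bulk CSF flow.** Production `Q_CSF` in the ventricles (entering as
  solute-free fluid), advection ventricles → cisterna, splitting into
  `φ_CR · Q_CSF` (cisterna → cranial SAS → absorption; `φ_CR` = 0.75) and
  `(1 − φ_CR) Q_CSF + Q_leak` (cisterna → spinal SAS), with spinal efflux
  `(1 − φ_CR) Q_CSF` (absorption) plus `Q_leak` (catheter leak, 0–15 mL/h).
  The fluid imbalance a leak implies is absorbed into the constant-volume
  approximation.
* **Oscillatory mixing.** Symmetric exchange flow `Q_osc` on the
  cisterna↔cranial and cisterna↔spinal connections (cardiac/respiratory
  mixing without net transport).
* **Withdrawal events.** Each 6 mL draw displaces its volume down the
  advective chain instantaneously: spinal CSF is replaced from the
  cisternal side (`C_SP += (draw/V_SP)(C_CIS − C_SP)`), cisternal from the
  ventricular side, ventricular volume is made up by fresh solute-free CSF.
  A spinal-only replacement rule is a no-op at steady state (all downstream
  compartments share one concentration), so it cannot reproduce the
  well-documented depletion of lumbar Aβ by serial sampling; the cascade
  yields ~9% depletion over 36 h at defaults.
* **Measurement.** Predicted lumbar concentration is
  `SF_40 × C_SP × 4.3298·10⁶ pg/nmol`; `SF_40` is a mass-spec calibration
  scale that cancels in the labeled fraction.

CSF compartment volumes are age-linear, `V = f_VCSF (a + b·age)`, with
coefficients in the packaged config chosen so ventricular + cisternal +
cranial-SAS volume is 150 mL at age 70 (35 + 15 + 100), growing ~1 mL/y.
`f_VCSF` (0.5–1.25) represents error of that regression. Spinal SAS volume
`V_SP` (40–100 mL) is a separate unknown.

**Numerics.** Because the system is linear, the simulator propagates with
matrix exponentials on a uniform node grid (default step 0.25 h; every
sample time on a node), treating the production forcing as piecewise linear
between nodes — for step operators `Φ = e^{Ah}`, `S₀ = ∫₀ʰ e^{A(h−s)}ds`,
`S₁ = ∫₀ʰ e^{A(h−s)}s ds` the update is exact up to the forcing
interpolation. This is deterministic, free of solver-tolerance jitter, and
fast enough (~0.2 ms per 36-h study) to sit inside the grid fit's inner
loop. Irregular (actual-time) schedules fall back to per-interval
operators. The test suite cross-checks against an adaptive LSODA
integration of the same right-hand side at tight tolerances.

Steady state solves `A c = −u` directly; mass balance (production equals
the sum of ISF first-order loss, cranial and spinal absorption, and leak
efflux) holds to numerical precision and is asserted to 0.1% over random
admissible parameter sets.

With default parameters the model produces: lumbar Aβ40 ≈ 6.5 ng/mL,
ISF:lumbar concentration ratio 2.3 (microdialysis supports 3–4), lumbar
labeled-fraction peak at ~20 h (observational SILK studies report ~25 h),
fixed-window FSR ≈ 0.038/h (historical amyloid-positive mean 0.0361/h).

## 3. Production-rate estimation (grid fit)

Per subject, the three structural unknowns (`f_VCSF`, `V_SP`, `Q_leak`)
are held at every combination of their grids — 4 × 4 × 4 — and `k_BPD40`
is restricted to a low (0.05–0.2 /h) or high (0.2–0.35 /h) regime, giving
128 constrained optimizations. Each adjusts (`k_BPD40`, `SF_40`, `Q_CSF`,
`Q_osc`) by Nelder–Mead (adaptive variant; log coordinates for `SF_40`,
`Q_osc`; logit-bounded coordinates for `k_BPD40` within its regime and
`Q_CSF` within 8–60 mL/h; deterministic restart of the simplex at the
incumbent optimum, which is the standard remedy for valley stalls).

The fitted data are (i) all non-missing SILK labeled fractions over
0–36 h and (ii) lumbar Aβ40 concentrations that are non-missing, within
0–15 h, and drawn at or after the first 11:00 local time after catheter
placement (concentrations earlier that morning carry the previous night's
sleep effect; later concentrations are sleep-confounded and excluded by
the 15-h window).

Objective: `J = SSR_silk/ν_s + SSR_conc/ν_c + penalties`, where both SSRs
are sums of squared **standardized** residuals — residual divided by the
observation (floored at 10⁻³ for the structurally-near-zero early labeled
fractions). Measurement noise is proportional in both channels, so
standardization puts them on one statistical scale; with raw residuals the
concentration channel (pg/mL scale) outweighs the SILK channel by ~10⁹ and
the fit chases concentration noise. Penalties:

* `w · max(0, ISF:lumbar − 10)²` — implausible ISF:lumbar ratios (>10 is
  unsupported by microdialysis) otherwise produce runaway production
  estimates; the ratio is evaluated at the pre-infusion steady state;
  `w` = 1 on the per-point-normalized objective scale, where any unit of
  ratio excess dwarfs the data terms (~10⁻²).
* `(ln SF_40)²` — the data determine only the product `SF_40 · R_APP`
  (the labeled fraction is scale-free and the production rate is profiled
  from the concentration scale), so the objective is otherwise exactly flat
  along `SF_40`; anchoring the calibration factor at 1 makes absolute
  production identifiable. This encodes the assumption that mass-spec
  calibration error is modest — the assumption under which an absolute
  production rate is reportable at all.

`R_APP` is profiled analytically at every evaluation (the model is linear
in production): `R̂ = mean(observed conc) / (SF_40 · mean(predicted conc at
R_APP = 1))`, keeping the four named adjustable parameters as the simplex
coordinates.

Selection: converged fits whose SILK **and** concentration SSRs both lie
within 20% of the respective minima are kept and their production rates
averaged (arithmetic mean). If the two bands select disjoint sets, the
single best-objective record is used and flagged. Rank order is recorded
for reporting only.

**Identifiability, honestly stated.** With bi-hourly 36-h data at 7.5%
proportional noise, the low- and high-clearance regimes are only weakly
discriminated, and `Q_leak` (which scales the steady-state ISF:lumbar
ratio as `(1 + Q_CSF/k_t)(1 + Q_leak/Q_CSF)`) is the main residual source
of production-estimate dispersion: per-subject recovery error is typically
8–15% (median) with occasional 2× outliers when a wrong-leak fit wins both
residual bands. The reduced 8-combination grid used by the test suite and
replicate experiments spans `f_VCSF` {0.75, 1}, `V_SP` {40, 80},
`Q_leak` {0, 10} with the low-clearance regime, since the synthetic
population's clearance lies there; the full 128-combination grid is the
production configuration and is exercised on single subjects.

## 4. Fractional synthesis rate

FSR = OLS slope of the labeled-fraction upslope ÷ plasma-leucine plateau
enrichment (mean over hours 4–9 of infusion). The normalization follows
standard SILK practice; the prespecified window is hours 6–16. The
automated variant smooths with a 3-point running median, takes first
differences, finds the contiguous positive run containing the steepest
rise, trims run edges rising at <20% of that steepest rise (the flat
lead-in before label arrives and the rollover into the peak are not
upslope), and widens symmetrically to ≥4 samples, earliest first. On
noise-free simulator output the two variants agree to ~12%; a <20%
disagreement band held in 50/50 noisy draws during development. Missing
draws are dropped, never interpolated.

Newly synthesized Aβ multiplies the catheter-placement plasma/CSF
concentration by the labeled fraction per time point; its AUC uses the
linear trapezoid on observed points.

## 5. Noncompartmental PK

Linear trapezoid AUC(0–24) on observed points (no extrapolation; log-down
available behind a flag), Cmax/Tmax with earliest-time tie-breaking, λz by
log-linear regression over all suffixes of ≥3 positive concentrations
strictly after Tmax choosing maximal adjusted r² and requiring a negative
slope, t½ = ln2/λz, Cl/F = dose/AUC (mg→ng, mL→L reconciled), Vz/F =
Cl/F/λz. Values below quantification are treated as missing. Arm-level
summaries are geometric mean with %GCV = 100·√(exp(s²_ln) − 1) (sample
variance of logs); Tmax is median (min–max).

## 6. Trial statistics

* Baseline 2×2 tables: Pearson χ² without continuity correction
  (`n(ad−bc)²/` margin product) and the two-sided Fisher exact test (sum of
  hypergeometric probabilities ≤ the observed table's); both are exposed
  because published small-trial baseline tables mix the two.
* Continuous baseline rows: pooled-variance two-sample t computable from
  printed summaries (mean ± SD, n).
* Change-score ANCOVA: OLS of change on treatment + age + sex (baseline
  MMSE behind a flag; the primary adjusted model uses age and sex). LS
  means are model predictions at covariate means. A degenerate perfect fit
  returns difference 0, p 1.
* Dose–response: OLS of the production estimate on dose-arm indicators +
  pre-treatment lumbar Aβ40, reporting adjusted contrasts vs placebo.
* Power: two-sided pooled-t power via the noncentral t with noncentrality
  `(pct·mean/sd)·√(n₁n₂/(n₁+n₂))`. With the historical FSR scale
  (0.0361 ± 0.00954) a 27% shift gives power 0.39 at 5 vs 9 and 0.64 at
  15 vs 9 — the module computes the quantity; no published power claim is
  asserted.
* No multiplicity adjustment anywhere (none was applied in the setting
  this mirrors).

## 7. Synthetic cohort

The generator emulates a three-cohort sequential ascending-dose design:
per cohort, eight amyloid-eligible subjects (CSF Aβ42/40 < 0.131;
screening draws ~N(0.112, 0.018) with ineligible candidates rejected) are
randomized 5 active : 3 placebo in permuted blocks stratified by site, the
active arm being 60 mg QD, BID, or TID by cohort — 24 randomized subjects,
9 placebo. The default site list is a single stratum so each cohort is one
complete block realizing 5:3 exactly; multi-site stratification is
implemented and tested separately.

Per-subject truth: production `R_APP` lognormal (median 1 nmol/h, CV 0.20)
times the arm's fractional reduction (0/10/20/30% for
placebo/QD/BID/TID); `k_BPD40` lognormal (median 0.08/h, CV 0.15, clipped
to the admissible range); `Q_CSF` normal (20 mL/h, CV 0.10); `Q_osc`
lognormal (30 mL/h, CV 0.20); `V_SP` uniform on {40, 60, 80, 100} mL and
`Q_leak` uniform on {0, 5, 10, 15} mL/h — the population the estimation
grid was designed to span (leaks and volume errors are hypothesized
precisely because they occur); `f_VCSF` lognormal (CV 0.08) for
age-regression error; `SF_40` = 1 (measurements calibrated on average).

Leucine enrichment follows a one-pool primed-infusion curve with plateau
0.12 and pool turnover 0.6667/h (at which the 3:2 bolus:rate ratio primes
exactly); it decays mono-exponentially after 9 h. Enrichment magnitudes
are config, not data-derived.

Measurement model: multiplicative lognormal noise, unit mean, independent
across time points — CV 7.5% on labeled fractions (truncated to [0, 1]),
10% on concentrations; one Bernoulli(0.1825) missing-draw indicator per
scheduled time knocks out all CSF analytes at that draw (plasma sampling
is complete), matching the ~81.75% CSF completeness the design
anticipates. Drug PK is superposed one-compartment first-order-absorption
profiles at steady state (21 days of dosing, last dose at catheter
placement): parent ka 1/h, ke 0.198/h (t½ 3.5 h), Cl/F 280 L/h sized so QD
60 mg gives a ~9 ng/mL 24-h mean plasma concentration; N1/N8 as
formation-fraction-scaled analogues; CSF at a fixed plasma ratio. These
are plausibility-scale settings, never asserted as equalities. Biomarker
change scores (screening vs catheter placement) carry a small
translational-inhibition signature (Aβ down, sAPP/tau up on active).
Start-of-experiment clock times are drawn from {9:00 … 11:00}. An optional
sinusoidal circadian production modulation exists and is off by default.

**What the synthetic experiments show.** Parameter-recovery and ordering
experiments validate the estimation pipeline against known truth under
the stated noise/missingness conditions with the same model family that
generated the data. They do not test structural mis-specification (a real
brain is not five well-mixed compartments), assay drift, circadian
production, or plaque-mediated Aβ42 exchange — all outside the generator.

## 8. Replicate experiment design

* **Recovery**: the full default cohort (24 subjects, all variability on)
  is fitted with the reduced grid; the median absolute relative error of
  averaged production vs truth is the headline accuracy (typically
  10–20% depending on the seed, with occasional per-subject 2× outliers).
* **Dose-ordering**: 20 seeded replicate cohorts are generated with the
  between-subject production CV set to zero, isolating the dose signal:
  each arm's true production is exactly the median times its reduction, so
  "the estimates reproduce the simulated monotone ordering" is a property
  of the estimator, not of sampling luck. (With the default CV of 0.20 and
  n = 5 per arm, the *realized* arm medians themselves are non-monotone in
  roughly half of replicates — adjacent true gaps of ~1–5% occur
  routinely — so the isolated-signal design is the version of the
  experiment that measures the pipeline.) All other variability
  (structural parameters, noise, missingness) remains at defaults.
  Even so, the experiment is demanding: per-subject dispersion of ~10–15%
  (§3) leaves arm-median errors comparable to the 10% dose gaps at n = 5,
  and strictly monotone estimated medians were observed in about half of
  replicates during development — an honest picture of what arms of five
  can resolve with this estimator.

## 9. Known limitations

* The compartment topology is a concrete stand-in honoring the named
  processes; absolute production estimates inherit the `SF_40 ≈ 1`
  calibration assumption and the fixed structural constants (`k_t`,
  `V_ISF`, `φ_CR`, volume coefficients).
* The high-clearance `k_BPD40` regime can overfit noisy curves and win the
  selection band with inflated production; the regime split exists because
  both basins occur in real fits, and band-averaged estimates should be
  read with the dispersion the fit records expose.
* The automated upslope detector is a documented rule, not a published
  algorithm; its agreement with the fixed window is demonstrated on
  simulated curves only.
* NCA t½/Vz/F are undefined for profiles without a credible terminal
  phase (reported as missing, not imputed).
* The generator's drug PK and biomarker effects are scale plausibility
  devices for pipeline testing, not fitted to any dataset.
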