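# Methods

This note documents the models, conventions and numerical choices behind
each stage of the pipeline, what the synthetic-cohort generator does and
does not emulate, and the problem sizes the test suite uses.

## QT correction and change from baseline

QT shortens with heart rate; comparisons across time points therefore use a
rate-corrected interval. Fridericia's correction fixes the power-law
exponent at 1/3 (`QTcF = QT/RR^(1/3)`, RR in seconds, QT in ms). The
individual correction estimates the exponent per subject: all drug-free
replicate-level (QT, RR) pairs — the baseline day plus the first drug day's
predose extraction — enter an ordinary least-squares regression of log QT on
log RR, whose slope is `b` (`QTcI = QT/RR^b`). The regression is performed
on the log-log scale because the correction itself is a power law; it is
run on replicate-level pairs, not triplicate means, to use all available
information. Bazett's correction (exponent 1/2) is provided as an optional
method but is never a primary endpoint.

Corrected values used downstream are computed on the replicate-averaged
point: averaging first and correcting second is the documented order (the
two orders differ because the correction is nonlinear in RR). Changes from
baseline are strictly time-matched: a drug-day value at nominal time t is
compared with the baseline-day value at the same t, and times without a
baseline counterpart are dropped and logged rather than imputed. The Day-1
predose record is drug-free and is excluded from the delta analysis by
default.

## Central tendency

The repeated-measures model has a fixed mean per day-by-time cell, a random
subject intercept (compound-symmetric within-subject covariance), and
independent residuals, estimated by REML via `statsmodels.MixedLM`; both
drug days are modelled jointly. Least-squares means are the cell
coefficients; the one-sided 95% upper confidence bound is
`LS mean + t(0.95, df)·SE` with containment degrees of freedom
(subjects in the cell minus one). Degenerate inputs — zero variance, or no
subject with more than one observation — fall back to exact per-cell
one-sample summaries, which is also the model's analytic reduction for a
single time point.

The planning half-width uses the standard-normal quantile,
`z₀.₉₅·σ/√n`: at σ = 9 ms and n = 36 this gives 2.47 ms. The normal (rather
than t) quantile is deliberate — it is the only reading under which the
conventional "half-width < 2.5 ms at 36 subjects" arithmetic holds
(1.645·1.5 = 2.47 vs 1.690·1.5 = 2.53 with t₃₅).

## Categorical rules

All inequalities are strict; compound rules require both conditions. The
25% relative PR/QRS rules compare against the time-matched baseline value
and fall back to the subject's baseline-day mean when the matched time is
absent (the substitution is logged); with no baseline at all the relative
flag is missing while absolute flags are still computed. Incidence tables
count each subject at most once per category and day; the default
denominator is the number of subjects with at least one observation of that
metric on that day.

## Non-compartmental PK

AUC uses the linear-log trapezoidal rule: linear trapezoids on rising or
zero-bounded segments, the logarithmic trapezoid `(C₁−C₂)Δt/ln(C₁/C₂)` on
strictly positive declines. Predose below-quantitation values are taken as
0; zero concentrations embedded or trailing after the first positive value
are excluded from AUC and terminal-slope estimation. The terminal slope λz
is chosen automatically: candidate sets are the last k ≥ 3 positive
concentrations strictly after Tmax; the set maximising adjusted R² wins,
preferring sets spanning at least two estimated half-lives when any such
set exists; flat or rising tails yield a "not estimable" flag rather than
an exception. `AUC₀₋∞ = AUC₀₋last + C_last/λz`, with the extrapolated
fraction recorded. Tmax is the first time of the maximum on ties. The
accumulation ratio is the Day-10 over Day-1 AUC across the same 0–10 h
window. Geometric summaries use `exp(mean log)` and
`CV% = 100·√(exp(s²_log) − 1)`; Tmax is summarised as median (min, max) and
half-life and accumulation ratio as arithmetic mean (SD). Metabolite/parent
ratios are arithmetic means of per-subject ratios (a ratio of group means
is a different, non-equivalent statistic).

## Exposure–response models

For subject i, record j:
`y_ij = θ₀ + f(C_ij; θ) + η_i + ε_ij`, `η_i ~ N(0, ω²)`, `ε_ij ~ N(0, σ²)`,
with structural forms f = 0 (no effect), θ₁C (linear), Emax·C/(EC50+C), and
Emax·C^γ/(EC50^γ+C^γ). Only the intercept carries between-subject
variability, and the residual model is additive — appropriate on the ΔQTc
scale.

Because the single random effect is additive and Gaussian, the marginal
likelihood is exactly multivariate normal with per-subject covariance
σ²I + ω²11′. The package therefore maximises the exact marginal likelihood
in closed form rather than via quadrature or linearisation: for fixed
variance ratio φ = ω²/σ² and fixed nonlinear parameters (EC50, γ), the
linear coefficients are profiled out by GLS (using the Woodbury form of the
compound-symmetry inverse) and σ² by its ML expression, leaving a 1–3
dimensional outer optimisation (bounded scalar search over log φ; multistart
Nelder–Mead over log EC50 and log γ, with γ soft-bounded to [0.1, 10] and
EC50 starts at quantiles of the positive concentrations). An EC50 outside
[C_min/100, C_max·100] raises a boundary flag. Standard errors come from
the inverse of a central-difference Hessian of the exact negative
log-likelihood in natural parameters; Wald intervals use the normal
quantile. The objective function value (OFV) is −2 log L including the
2π constant, so only OFV differences are meaningful.

Model selection: nested pairs (no-effect under everything; Emax under
sigmoid Emax) by likelihood-ratio test at α = 0.05 per added parameter
(ΔOFV > 3.84 per df); non-nested pairs by AIC; ties favour fewer
parameters. These thresholds are defaults and configurable. Covariates
(sex, BMI, ECOG) are screened as additive intercept shifts by forward
addition with a 1-df LRT at p < 0.01; constant covariates are skipped and
logged. The heart-rate model applies the same machinery to HR with a freely
estimated population intercept.

The subject-resampling bootstrap redraws subjects with replacement, refits,
and reports per-parameter medians with 5th/95th percentiles plus a 90%
band for the fitted line over the observed concentration range; replicates
that fail to fit are dropped, with a warning above a 20% failure rate. The
seed governs resampling only — fits themselves are deterministic.

## Effect-size simulation

Simulated patients draw `θ₀ + f(C_ref) + η + ε`, i.e. both variance
components are included, so the simulated SD is on the total scale
(ω 7.17 ms and σ 6.5 ms give √(ω²+σ²) ≈ 9.68 ms). This is the
interpretation consistent with a reported simulated-population SD close to
the total rather than the between-subject SD alone. Percentiles use linear
interpolation between order statistics; CV% is 100·SD/|mean|, reported
missing when the mean is exactly 0; exceedance percentages use strict
inequalities, with `tail_probability` providing the analytic normal-tail
limit. The default reference concentration is 2760 nM (steady-state
geometric-mean Cmax of the emulated regimen at 50 mg BID).

## The synthetic cohort generator

The generator defines the study conditions for all tests; its defaults are
fixed, not tuning knobs.

**Design.** 50 subjects; triplicate ECG extractions on Days −1/1/10 at
0, 0.5, 1, 2, 3, 4, 6, 8, 10 (and 24 on Days −1/1) hours; PK samples at the
same times through 72 h on Day 1 and through 10 h on Day 10; one dose on
Day 1, BID doses Days 4–9, a morning dose on Day 10. Baseline times must
cover the drug-day times up to 24 h so time matching is possible.

**PK.** One-compartment, first-order absorption, linear elimination,
multiple doses by superposition; this is the simplest structure
qualitatively consistent with the emulated profile (no structural PK model
is implied by NCA summaries). Defaults: ka 0.75 h⁻¹, CL/F 2.494 L h⁻¹,
V/F 59 L — i.e. t½ = 16.4 h and a continuous-time single-dose Tmax of
≈ 4.06 h, which the sampling grid snaps to a median Tmax of 4 h; a 50 mg
dose converts to nM with 10⁶/518.92 per mg L⁻¹ and gives a Day-1
geometric-mean Cmax near 1.5 μM. One log-normal deviate (CV 41%, median
preserved) scales CL/F and V/F jointly, so the elimination rate, Tmax and
t½ are preserved per subject and the whole profile scales log-normally —
making the between-subject CV of any exposure metric equal the nominal CV
exactly, which the tests exploit. Metabolites are scaled copies of the
parent with their own absorption and elimination rates (M1: scale 0.45,
t½ 16.4 h; M2: scale 0.41, ka 0.23 h⁻¹, t½ 22 h), sharing the parent's
subject deviate so per-subject metabolite/parent exposure ratios equal the
scale by construction; there is no mechanistic formation model. Observed
AUC₀₋last ratios sit slightly below the scale for M2 because the 72 h
cutoff truncates more of its longer tail.

**ECG.** Subject exponents b are log-normal (mean 0.35, SD 0.06 — the
physiological range of individual QT/RR exponents); QT at RR = 1 s is
400 ms. RR follows a circadian cosine (mean 0.90 s, amplitude 0.07 s,
maximum at 04:00, dosing clock-anchored at 08:00) plus N(0, 0.05 s)
per-time-point noise and N(0, 0.015 s) replicate noise; the spec of the
replicate structure — triplicates share the time point's RR draw up to
replicate noise — requires these two RR noise scales. QT noise is
N(0, 5.7 ms) per time point (shared by the triplicate) plus N(0, 5 ms) per
replicate, chosen so the SD of a time-matched triplicate-mean delta is
≈ 9 ms, the canonical planning value: Var(Δ) = 2(5.7² + 5²/3) ≈ 81. PR and
QRS are Gaussian (160 ± 5 ms, 95 ± 4 ms). An injected drug effect (linear
slope or Emax in the model-predicted concentration at the same nominal
time, with no PK measurement error in the linkage) shifts drug-day QT.
Covariates: sex ~ Bernoulli(0.64 female), BMI log-normal (median 27,
CV 20%), ECOG ~ Bernoulli(0.5).

**What it does not emulate.** QT/RR hysteresis, food effects, dropout
beyond an evaluability flag, assay error in the PK-ECG linkage,
measurement-time deviations from nominal, and — deliberately — the
supralinear accumulation seen in some observed datasets: linear kinetics at
t½ = 16.4 h and τ = 12 h give an accumulation ratio of ≈ 2.5, and the
generator makes no attempt to reproduce larger observed values (≈ 3.5),
whose mechanism (possible nonlinearity) is not characterised. Passing tests
therefore demonstrate correctness of the estimators and the pipeline's
operating characteristics under this idealised data-generating process, not
agreement with any particular clinical dataset. The generator's day-10
exposures are whatever linear superposition implies.

Determinism: a root `SeedSequence` per cohort spawns child streams per
subject; identical configs and seeds reproduce byte-identical CSV output
(fixed float format, fixed line terminator).

## Problem sizes used by the tests

The simulation suites run at the sizes their statistical statements are
calibrated to: 200 seeds for the exponent-recovery, null-coverage,
selection-specificity/sensitivity and UCB-coverage suites (50 subjects × 10
observations each); 100 outer replications with B = 200 for bootstrap
coverage; 100 cohorts of 100 subjects for Emax recovery; n = 2000 subjects
for the exposure-CV convergence check; n = 10⁵–2·10⁵ draws for
law-of-large-numbers checks. Integration tests use 12–20 subject cohorts
with B = 10–50 bootstrap replicates. The acceptance script runs the full
pipeline at the design's 50 subjects with B = 200 and 1000 simulated
patients.

## Known limitations

* The mixed model for central tendency assumes compound symmetry; serially
  correlated within-day errors would need an AR structure the package does
  not implement.
* Between-subject variability is restricted to the model intercept (no
  random slope/Emax), matching the reporting convention of no-effect-model
  summaries; richer random-effect structures are out of scope.
* Emax/sigmoid-Emax fits on data with no true saturation are weakly
  identified; the EC50 boundary flag marks such fits, and near-flat
  degenerate solutions are handled by the likelihood-ratio guard in model
  selection rather than by hard constraints.
* The categorical denominators default to subjects observed on the day;
  alternative denominators (all dosed subjects) are a report option left to
  the caller.
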