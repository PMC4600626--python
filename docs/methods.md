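# Methods

## Model overview

The pipeline estimates the association between intrinsic epigenetic age
acceleration (IEAA) and incident disease in five stages. Stages 1–4
construct the exposure; stage 5 is the inferential model.

**Beta values.** β = max(M,0)/[max(M,0)+max(U,0)+100]. The +100 offset
regularizes low-intensity probes, so β ∈ [0,1) and the formula is
deliberately not invariant to intensity rescaling.

**Age transform and clock.** The clock operates on
F(age) = log(age+1) − log(a+1) for age ≤ a, (age−a)/(a+1) otherwise, with
knot a = adult_age = 20 (configurable; must exceed −1). F is continuous,
strictly increasing, and zero at the knot; its inverse is applied to the
clock's linear predictor to report DNAm age in years. `apply_clock` joins
on probe IDs (order and extraneous probes are irrelevant), imputes missing
clock probes by the cohort mean of that probe (fallback 0.5 when a probe is
missing everywhere; a "midpoint" policy is available), and flags — rather
than silently NaN-ing — any sample with fewer than 80% of clock probes
observed. Imputation policy is this package's decision; published cohort
analyses typically do not document theirs. No copyrighted coefficient set
ships with the package: any coefficient CSV in the standard two-column
format ("(Intercept)" row plus CpG rows) is accepted, and
`train_clock` fits an elastic net (mixing 0.5, penalty by seeded 10-fold
cross-validation) on synthetic cohorts.

**Cell deconvolution.** Composition w solves min‖β − Rw‖² s.t. w ≥ 0
(and Σw = 1 in the default `sum1` mode, treating the seven leukocyte types
as exhaustive for whole blood; a `free` mode with nonnegativity only is
provided because methylation-imputed abundances need not sum to one).
The solver is nonnegative least squares with the sum constraint imposed by
an appended penalty equation. The penalty weight is 1e4 scaled by the
Frobenius norm of the reference on the shared probes: the gradient of the
fit term grows with probe count, so a fixed weight would let the row-sum
violation grow past 1e-8 for references of a few hundred probes, while the
scaled weight keeps it below 1e-8 regardless of size (verified against a
dense simplex grid-search oracle in the tests). The original
methylation-imputation method estimates two of the seven types (exhausted
CD8 T, plasmablasts) by penalized regression on a separate training set;
this package treats all seven uniformly through the signature matrix,
which is a documented divergence.

**IEAA.** OLS of DNAm age on [1, age, cell fractions]; the residual is
IEAA, standardized by the sample SD (n−1) over the full analyzed cohort.
Stratified analyses reuse the full-cohort standardization so hazard ratios
across strata share one scale. When fractions sum to one they are exactly
collinear with the intercept; the granulocyte column (the majority
fraction) is dropped to restore full rank. Remaining rank deficiencies
raise an error naming the dependent columns. Samples failing clock
application are excluded listwise; standardization happens after
exclusions (configurable in principle via the inputs supplied). By
construction the residual is orthogonal to age and each included cell
regressor, and is exactly invariant to adding constants to all DNAm or
chronological ages.

**Survival models.** Cox proportional hazards with Breslow tie handling
(lifelines backend; Efron is available through the same backend), with
damped-Newton retries (step 0.5, then 0.25) when the default full step
oscillates on near-collinear designs such as smoking dummies vs
pack-years. The Breslow baseline cumulative hazard and the null partial
log-likelihood are computed in-package from the fitted coefficients; the
reported R² is the Cox–Snell-family index 1 − exp(2(ll₀ − ll₁)/n),
labeled explicitly because publications using an "R²" row rarely define
it. Reference categories are never-smoker and non-Hispanic white. Age
strata are left-closed ([50,60), [60,70), 70+); the conventional labels
"50–59" etc. do not state boundary handling, so this is the package's
choice. Within a stratum, covariates that are constant (e.g. pack-years
among never smokers, which is zero by definition) are dropped and
recorded; unestimable strata (no subjects or no events) are reported as
such, never silently omitted. Covariate-profile incidence is
1 − exp(−H₀(t)·exp(xᵀβ)), a right-continuous step function extended flat
(with a warning) beyond the last observed follow-up time. Person-time is
days/365.25 rounded to four decimals. Sensitivity analyses: landmark
exclusion of cases within k years of baseline (censored subjects always
retained), and logistic regression of the event indicator on the same
covariates (for a rare outcome the odds ratio approximates the hazard
ratio; verified empirically in the tests). A Bonferroni threshold of
0.05/6 across the six stratified tests can be applied by the caller; it is
reporting, not a gate.

Biweight midcorrelation uses weights (1−u²)² for |u| < 1,
u = (x − median)/(9·MAD), and a Student-t p-value with n−2 df; zero-MAD
inputs fall back to Pearson with a warning (or raise, configurably).
Kruskal–Wallis is tie-corrected with a χ²(k−1) p-value and refuses
all-identical data, where the tie correction degenerates.

## Synthetic cohort generator

The generator emulates the study population the pipeline targets:
postmenopausal women aged 50–79 (ages uniform), followed up to 20 years,
with a rare event (~2% cumulative incidence). Defaults: n = 2,000
subjects, 500 probes (60 clock probes), seven cell types, acceleration SD
5 years, logit-scale beta noise SD 0.05, planted hazard ratio 1.5 per SD
of acceleration, smoking prevalences never/former/current =
0.544/0.352/0.104, race prevalences white/Black/Hispanic =
0.477/0.319/0.204, CHD prevalence 0.31, mean pack-years 19.4 (former) /
25.9 (current) drawn Gamma(shape 2) among ever-smokers and exactly zero
for never smokers. These match the baseline table of the cohort the
pipeline emulates.

*Signatures.* Reference profiles use a Hadamard-pattern discriminative
block (high 0.9 / low 0.1, ±0.02 jitter): any two distinct Hadamard
columns disagree in exactly half the positions, so every pair of cell
types differs by ≈0.4 mean absolute beta on the block — a deterministic
guarantee of pairwise separation ≥ 0.3. All other probes share a common
baseline across cell types and carry no composition signal.

*Cell fractions.* Dirichlet with concentration 50 around a realistic
blood composition (granulocytes ≈ 55%). An optional per-year log-shift
(`cell_age_dependence`) moves granulocytes up and naive CD8 T down with
age, emulating immunosenescent drift so tests can verify that
cell-adjustment (IEAA) removes composition confounding that the age-only
residual (EEAA) retains. Default 0 (composition independent of age).

*Beta composition.* Sample profile = expit(logit(Rw) + clock signal +
N(0, σ) noise). Noise lives on the logit (M-value) scale so outputs stay
strictly inside (0,1) without clipping artifacts. Two clock-signal modes:

- `logit` (default, the documented generative model): clock probe j gets
  slope sⱼ × (age + acceleration − 65) on the logit scale, sⱼ drawn
  ±U(0.01, 0.03) per year.
- `linear`: clock-probe betas are 0.5 + vⱼ(F(bio age) − F(65)) with
  vⱼ = ±U(0.05, 0.15), and `true_clock_model` returns the matching clock
  (cⱼ = vⱼ/Σv², intercept F(65) − ½Σcⱼ) satisfying intercept + Σcⱼβⱼ =
  F(bio age) *identically*. This mode exists because a linear-in-beta
  clock cannot be exact under the logit-scale signal (expit is
  nonlinear); it provides the noiseless-recovery oracle (machine-precision
  age recovery) and a clock stage with negligible attenuation for the
  end-to-end recovery experiment.

A `biology_seed` separate from the sampling seed lets independent cohorts
(different subjects and noise) share one underlying methylome — used to
draw disjoint training and test cohorts for clock fitting.

*Events.* Exponential event times (constant baseline hazard — the
simplest proportional-hazards-compatible choice, with closed-form checks)
with hazard = baseline_rate × exp(β_acc·z + covariate effects), z the
acceleration standardized by its population SD. Covariate log-HRs default
to values representative of a full-cohort lung-cancer model in a
comparable population (age 1.09/yr centered at 65, former smoker 2.22,
current 6.17, pack-years 1.03/yr, CHD 0.64, Black 0.87, Hispanic 1.25).
The default baseline rate (2.5e-4 events/person-year at reference
covariates) was calibrated once, numerically, so the default configuration
yields ≈2% cumulative incidence over 20 years — the incidence of the
emulated cohort. Administrative censoring at 20 years; observed times are
rounded to 4 decimals and floored at 1e-4 years. The latent acceleration
is Gaussian and time-constant per subject (the exposure of interest is a
baseline scalar, so no trajectory modeling). The emulated study's
two-phase case–control sampling for CHD and its survival-to-collection
requirement are *not* modeled: the generator produces a simple prospective
cohort.

## Validation experiments and problem sizes

- **End-to-end recovery** (`experiments.endtoend_recovery`): 50 replicates
  of n = 2,000 with planted HR 1.5/SD, `linear` clock mode with the known
  clock. With a *trained* clock at held-out r ≈ 0.9 the proxy-variable
  attenuation alone (estimated HR ≈ 1.5^ρ with ρ the IEAA–truth
  correlation) would dominate the comparison; the near-exact clock stage
  isolates the survival estimator, whose mean HR falls in [1.40, 1.60]
  with 95%-interval coverage in [90%, 99%].
- **Type-I error** (`experiments.null_rejection_rate`): 500 replicates of
  the honest full pipeline at reduced size (n = 500, 120 probes, baseline
  rate raised to 2.6e-3 for ≈15% incidence, ~70 events per replicate so
  Wald asymptotics are exercised); rejection at α = 0.05 in 3–7% of
  replicates.
- **Clock training** (`experiments.clock_heldout_correlation`): train on
  500 subjects, test on 200 from the same methylome; held-out age
  correlation ≥ 0.9.
- **Deconvolution** (`experiments.deconvolution_mae`): 200 noisy 7-type
  mixtures; mean absolute fraction error ≤ 0.05 (measured ≈ 0.003).
- **IEAA recovery** (`experiments.ieaa_truth_correlation`): n = 1,000 with
  logit noise SD 0.5, calibrated so the clock explains ≈90% of
  biological-age variance; correlation with the planted acceleration
  ≥ 0.8.

These sizes are the package's chosen experiment designs; all are driven by
a single seed and complete in about a minute.

## What the synthetic validation does and does not show

The generator plants exactly the structure the pipeline assumes: linear
mixtures over a known reference, a (log-)linear age signal, exponential
proportional hazards, independent logit-Gaussian noise. Passing tests
therefore demonstrate correctness of the estimators under their own
assumptions and calibrated uncertainty at realistic event counts — not
robustness to array artifacts, batch effects, probe cross-reactivity,
reference mis-specification, non-proportional hazards, competing risks, or
informative censoring, none of which are simulated. There is no
idat-level simulation, no normalization step, and no missing-data
mechanism beyond optional uniform masking.

## Numerical choices

- Sum-to-one deconvolution: penalty row 1e4·‖R‖_F; row sums within 1e-8;
  nonnegativity enforced by the active-set NNLS solver, not by clipping.
- Zero-variance IEAA residuals are detected at 1e-10 relative to the
  response scale (exact fits leave ~1e-13 numerical residue).
- Cox convergence: lifelines Newton default, then step 0.5 / 0.25 retries;
  remaining failures raise a monotone-likelihood diagnostic. Constant
  covariates and rank-deficient designs are rejected up front with names.
- All generator randomness flows through numpy Generators seeded as
  (seed, stage-stream); identical configs are bit-reproducible, and the
  pipeline manifest records a sha256 checksum of every artifact.
- Pipeline config validation is performed by explicit structural checks
  (collected and reported together) rather than a JSON-schema dependency.
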