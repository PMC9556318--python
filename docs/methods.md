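# Methods

This note documents the statistical model implemented by `burden_of_proof`,
the defaults that matter, the numerical choices, and what the synthetic-data
experiments do and do not demonstrate.

## Observation model

An observation is one reported ratio measure (RR, OR or HR) comparing an
alternative exposure interval `[a0, a1]` with a reference interval
`[r0, r1]` (usually the degenerate never/zero-exposure point).  All modelling
is on the log scale; a reported 95% CI (L, U) is inverted to a log-scale
standard error `se = (ln U − ln L) / (2 × 1.959964)` under log-normal
sampling.  When both a CI and an se are extracted, the CI wins and a >1%
disagreement is logged.  Open-ended top categories (">x") are closed by adding
the study's median closed-interval width to the threshold, falling back to
1.5×x; the imputation is flagged on the interval.  Exposure units
(pack-years or cigarettes per day) must be harmonized upstream; the package
validates consistency only.

## Stage 1: ensemble-spline signal

The dose–response shape ("signal") s(x) is a cubic spline anchored at
s(0) = 0 — zero exposure is the theoretical minimum risk level, so log RR(0)
must vanish.  s is parameterised through its derivative expanded in a
quadratic B-spline basis: s(x) = Σ_k c_k ∫₀ˣ M_k(t) dt.  Nonnegative
(nonpositive) weights c then give a nondecreasing (nonincreasing) curve
exactly, so the monotone constrained weighted least-squares problem is a
nonnegative least-squares problem (scipy's `nnls`), with an ordinary `lstsq`
for unconstrained pairs.  An observation's design value is the exact
polynomial interval average of s over its alternative interval minus that
over its reference interval (point evaluation for degenerate intervals);
beyond the last knot the curve continues linearly at the boundary slope.

Robustness: a pilot member with interior knots at the 25/50/75% exposure
quantiles iteratively trims the ⌈trim_fraction × n⌉ observations (default
10%) with the largest |standardized residual|, refitting until the trimmed
set is stable (≤20 iterations).  The ensemble then fits `n_ensemble` members
(default 50) on the shared untrimmed set, each with 2–4 interior knots placed
uniformly between the 10th and 90th exposure-midpoint quantiles (seeded;
minimum knot gap 1% of the span).  Member weights are
`log w_j ∝ −0.5 n log MSE_j − λ_TV · TV_j` (softmax-normalized), where TV_j
is the exact total variation of s′ (the integral of |s″|) and λ_TV = 0.1;
fit dominates, total variation discourages wiggly members.  If the fitted
ensemble is numerically flat (a possibility under a pure-noise null, where
the sign constraint can zero every coefficient), a unit linear ramp is
substituted so the downstream slope remains defined; the slope estimate is
then ≈0 and the pair grades one star, which is the correct behaviour.

## Stage 2: bias covariates

Bias covariates (0 = gold-standard reference) cover the six GRADE risk-of-bias
domains plus subpopulation sampling, the adjustment level (number of
confounders adjusted for) and an age+sex adjustment flag.  They enter
multiplicatively on the shape — a biased study's expectation is
(β + c_k z_k)·s(x) — because quality problems plausibly rescale the whole
dose–response curve rather than shift it additively.  Selection is two-gated:
the common slope is partialled out of both the response and the interaction
columns (Frisch–Waugh), a Lasso whose penalty is chosen by 5-fold
cross-validation grouped by study is run on the standardized residualized
interactions, and surviving candidates must then be significant at α = 0.05
in an unpenalized mixed-model refit.  The refit covariance is evaluated at
the inflated heterogeneity γ* (below); with γ̂ itself the test is
anticonservative whenever γ̂ sits at its zero boundary.  Under the
generator's null the realized selection rate is ≈5%, and a covariate scaling
the signal by 1.5 in half of 50 studies is detected essentially always.
Predictions are made with selected covariates at their reference level.

## Stage 3: heterogeneity

With s_i the signal design value of observation i in study j,

    y_i = β s_i + Σ_k c_k z_ik s_i + u_j + v_j s_i + ε_i,
    u_j ~ N(0, τ²),  v_j ~ N(0, γ),  ε_i ~ N(0, se_i²).

Estimation is maximum marginal likelihood (not REML; the Fisher-information
bookkeeping is simpler and the simulation calibration below validates the
choice), with τ², γ ≥ 0, profiled fixed effects, and four deterministic
starts.  Because each per-study covariance is diagonal plus a rank-2 term
(U = [1, s], C = diag(τ², γ)), the likelihood is evaluated through the
Woodbury identity with all data-dependent pieces cached — only a 2×2
per-study system depends on the parameters.  β̂ ≈ 1 by construction since
the signal already carries the scale of the data.

SD(γ̂) is the square root of the (γ, γ) entry of the inverse Fisher
information of the variance components,
`I = 0.5 Σ_j [(1'W1)², (1'Ws)²; (1'Ws)², (s'Ws)²]` with W = V_j⁻¹.  The
*expected* information is used: it is positive semidefinite by construction
and remains meaningful at the γ = 0 boundary, where the observed (one-sided)
curvature is frequently negative; at an interior optimum the two agree (the
test suite checks 1e−4 agreement against a numeric Hessian on a balanced
design).  When the information matrix is singular — e.g. a signal constant
within studies, which confounds τ² and γ — the width of the half-unit
profile-likelihood step is used instead and logged.  Downstream uncertainty
uses γ* = γ̂ + 2·SD(γ̂): the convention that protects conclusions against
heterogeneity underestimated from few studies.  τ² is reported but not
propagated into the BPRF, whose contract concerns the slope distribution.

Simulation calibration (seeded, in the test suite): with γ = 0 and 50
studies, γ̂ < 0.01 in ≥90% of replicates; with γ = 0.04 and 100 studies the
median γ̂ is inside [0.02, 0.06]; intervals built from γ* cover the true
curve at the median exposure in ≥95% of replicates.

## Stage 4: publication bias

Fixed-effect residuals are paired with the heterogeneity-inclusive total SD
√(se_i² + γ* s_i²) — the funnel's y axis.  Egger's regression here is the
*unweighted* OLS slope of residuals on total SD with an intercept, tested
one-sided (positive for harmful, negative for protective) with a z statistic
whose standard error uses the known per-observation variances.  Unweighted,
because inverse-variance weighting suppresses exactly the noisy small studies
that carry the asymmetry signal and measurably destroys power against
selective reporting; the known-variance standard error keeps the test at
nominal size under heteroskedasticity.  Trimming runs first, so the flag
refers to asymmetry that survives outlier removal.  Fewer than five
observations yield an unflagged report with the reason recorded.  The flag is
diagnostic only; no correction is applied.

## Stage 5: draws, BPRF, ROS, stars

Draws β_d ~ N(β̂, var(β̂) + γ*) (default 1,000) define
log RR_d(x) = β_d s(x) on the dose grid 0–100 in steps of 0.1.  The mean
curve is the draw mean; the 95% UI takes the 2.5/97.5 draw percentiles (with
1,000 ranked draws, ranks 25 and 975).  The BPRF is the quantile curve of
the draw distribution closest to the null: for a harmful (nonnegative)
signal the 5th percentile, q₀.₀₅(β)·s(x); for a protective (nonpositive)
signal the same expression yields the 95th percentile curve.  The ROS
averages the signed log-BPRF over [p15, p85] of the alternative-interval
midpoints of untrimmed observations (percentiles by linear interpolation,
unweighted; the average by composite trapezoid with interpolated window
endpoints).  Stars: ROS < 0 → 1; 0–0.14 → 2; >0.14–0.41 → 3; >0.41–0.62 → 4;
>0.62 → 5.  The average BPRF is exp(ROS) for harmful and exp(−ROS) for
protective pairs, and the average increased risk is (avg BPRF − 1)×100% or
(1 − avg BPRF)×100% respectively.  Binary pairs skip the spline (the signal
is the smoker-vs-non-smoker indicator, trimmed against the weighted mean)
and halve their ROS so a single contrast is comparable to an
exposure-averaged one.

When published per-outcome summary rows are re-classified from their printed
two-decimal ROS, a value landing exactly on a star threshold is disambiguated
by the finer-grained average increased-risk column (percent thresholds
15/50/85 harmful, 13/34/46 protective).

## CVD age attenuation

The reference curve's age group is the 5-year bin containing the
1/se-weighted mean of per-observation assigned ages: cohort estimates use
baseline mean age plus mean/median follow-up (half the follow-up when only
its maximum was reported), case-control estimates the baseline midpoint.
The age pattern of excess risk (RR − 1, natural scale — chosen to match the
excess-risk ratio definition of the attenuation factor) is a quadratic
spline on age-bin midpoints (oldest open-ended bin: lower + 2.5) with
exposure-definition covariates (current/former/ever) and a study random
slope on age; predictions exclude the between-study component to keep the
attenuation pattern tight.  Attenuation factors are computed at the draw
level, AF_d(age) = excess_d(age)/excess_d(reference); draws with nonpositive
reference excess carry no usable ratio and are rejected, resampled and
counted.  Age-specific curves follow `RR_age = (RR_ref − 1)·AF + 1`
elementwise with draws paired by index (common random numbers), so AF
uncertainty propagates into the age-specific UIs.

## Synthetic data

`TruthSpec` defaults define the simulated study conditions: 30 studies × 4
observations, log-linear truth with slope 0.04 per unit, τ² = 0.01,
γ = 0.01, reported SEs log-uniform on [0.05, 0.5], 10% outlier rows shifted
by ±U(3, 6)·se, a 15% chance per study of an open-ended top category, a 10%
chance of a ranged (low-dose) reference group, and study exposure ranges
drawn so the 85th percentile of exposure midpoints sits near 43 units
(within the 30–50 band typical of the summary tables).  Censoring, when
enabled, drops rows whose CI covers 1 *and* whose se is above the 67th
percentile — a small-study reporting-bias mechanism.  The censoring
experiments use a weak truth (slope 0.01) because with the default strong
effect almost every row is significant and the rule is vacuous.  Simulation
studies in the tests and the acceptance script use 5-member ensembles
(single-fit tests exercise the full 50) with 100–200 replicates per
scenario.

What passing these simulations does *not* show: the generator draws
independent Gaussian errors at the reported se, encodes bias as clean
study-level binary shifts, and knows the true curve family.  Real
extractions violate all three (correlated estimates sharing denominators,
misreported uncertainty, bias that is neither binary nor multiplicative), so
the simulations validate the estimators' internal consistency and
calibration, not robustness to real-world extraction error.

## Numerical notes and limitations

- All randomness flows from one seed through `numpy.random.SeedSequence`
  spawning (stage order: knots, draws, age), so stages are individually
  reproducible and reruns are byte-identical.
- Trimming shrinks γ̂ mechanically (it truncates the residual tails); the
  heterogeneity-recovery calibration is therefore stated at the estimator
  level, before trimming interacts with it.
- The intercept–slope random-effect correlation is fixed at zero; one
  variance component must be dropped (`random_intercept=False`) when the
  signal is constant within studies, otherwise τ² and γ are confounded and
  SD(γ̂) falls back to the profile width.
- Multiple rows sharing one reference group within a study are decorrelated
  only through the study random intercept; no within-study residual
  correlation structure is modelled.
- No trim-and-fill or selection-model correction for publication bias, no
  automatic knot-count selection beyond 2–4 interior knots, no Bayesian
  spline posterior, and no cross-outcome synthesis beyond the star scale.
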