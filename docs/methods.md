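# Methods

## The crosswise response mechanism

A respondent holds a latent sensitive indicator y ∈ {0,1} and an innocuous
indicator z ∈ {0,1} with known population prevalence p, independent of y
and of all covariates. The recorded answer is A when y = z and B
otherwise, so

λ ≡ Pr(A) = πp + (1 − π)(1 − p) = (1 − p) + (2p − 1)π,

with π = Pr(y = 1). The design is non-identifiable at p = ½ (λ ≡ ½
regardless of π); construction of a design rejects |p − ½| < 1e−9. The
degenerate ends p ∈ {0, 1} are permitted: they reduce to direct
questioning (possibly with complemented labels) and are used as algebraic
anchors in the tests.

## Prevalence estimation

The moment estimator inverts the line above: π̂ = (λ̂ + p − 1)/(2p − 1),
with SE(π̂) = SE(λ̂)/|2p − 1|. Because λ̂ can legitimately fall outside
[min(p, 1−p), max(p, 1−p)] by sampling noise, π̂ and interval bounds are
clipped to [0, 1] and flagged rather than raising.

Two intervals are offered:

- **Wald** (default): π̂ ± z·SE, truncated to [0, 1]. Under the study's
  conditions (n = 1454, π = 0.41, p = 0.24) its empirical coverage is
  within 1.5 points of 95% (checked by simulation in the test suite).
- **Wilson-transformed**: the Wilson score interval for λ mapped through
  the inversion. With p < ½ the inversion has negative slope, so the
  mapped endpoints arrive in reversed order and are swapped; an invariant
  test asserts ci_low ≤ π̂ ≤ ci_high for both p < ½ and p > ½.

Percent display rounds half away from zero to integers.

With cluster sampling, the ultimate-cluster estimator replaces the
binomial variance of λ̂: Var(λ̂) = k/(k−1) · Σ_c (t_c − m_c λ̂)² / n²
over k clusters with A-counts t_c and sizes m_c. The ratio of this to the
binomial variance is reported as the empirical design effect. Two-group
comparisons use the normal z statistic on the difference of independent
π̂'s.

## Crosswise logistic regression

Covariate effects on the latent trait follow a logistic model,
Pr(y = 1 | x) = σ(xβ). The observable answer then has
q(x) = (1 − p) + (2p − 1)σ(xβ), and β maximises the Bernoulli
log-likelihood in q. Numerical choices:

- Fisher scoring from β = 0 (where q ≡ ½ for every p), with step-halving
  whenever a step would decrease the log-likelihood, so accepted
  iterations ascend monotonically. The likelihood flattens as p → ½,
  hence defaults of 200 iterations and a score tolerance of 1e−8;
  non-convergence is flagged and a partial result returned with a
  warning, never silently.
- q is clipped to (1e−12, 1 − 1e−12) inside the likelihood.
- Standard errors come from the inverse *observed* information at the
  optimum, falling back to the expected (Fisher) information if the
  observed matrix is not positive definite. Wald CIs and p-values per
  coefficient; the OR table is exp of the coefficient and its limits.
- Categorical terms are dummy-coded against a declared reference level;
  age is modelled as single years 18–24 with reference 18 (a continuous
  coding is available by declaring the term without a reference). Rows
  with a missing response or any missing model covariate are dropped
  (listwise deletion) — the emulated study reported item non-response but
  no imputation.
- The default fit is marginal (no cluster adjustment). An optional
  cluster bootstrap (resampling clusters with replacement, 999 seeded
  draws by default) replaces the covariance when cluster-robust
  uncertainty is wanted.
- A profile log-likelihood diagnostic re-maximises the remaining
  coefficients over a grid for one term (the term enters as an offset);
  it warns when the grid does not bracket the MLE. Profiles sharpen as
  |2p − 1| grows — the information cost of privacy made visible.

Correctness is pinned by independent oracles rather than by comparison
with another crosswise implementation: a dense grid search over the
two-parameter likelihood, the exact reduction to ordinary logistic
regression at p = 1 (matched to statsmodels to 1e−6), the equivalence of
the intercept-only MLE with the moment estimator, and invariance under
relabelling A↔B with p ↔ 1 − p.

## Sample-size planning

n_base = ⌈ z²_{1−α/2} · p₀(1 − p₀) / d² · deff / response_rate ⌉ and
n_final = ⌈ n_base · crosswise_inflation ⌉, rounding up at every stage
and using the exact normal quantile rather than 1.96. With p₀ = 0.5,
α = 0.05, d = 0.05, deff = 2 and 80% response the formula gives 961; the
emulated study quotes 1000, which we read as the investigators' manual
rounding to the next hundred — the planner reproduces the formula value
and accepts an externally chosen base size for the inflation step
(1000 × 1.5 → 1500, allocated as 75 clusters of 20). The crosswise
variance premium itself is quantified by
`variance_inflation` = [λ(1−λ)/(2p−1)²] / [π(1−π)] ≥ 1, which at
p = 0.24, π = 0.41 is ≈ 3.8 — the *variance* cost of the design; the 50%
*sample-size* premium used in planning was the investigators' budgetary
choice, not this ratio.

## Synthetic-data generator

`simulate_survey` draws, per respondent: categorical covariates from
declared margins, a cluster random intercept u_c ~ N(0, σ_u²) on the
logit scale, y ~ Bernoulli(σ(xβ + u_c)), z ~ Bernoulli(p) independent of
everything, answer A iff y = z, then MCAR per-item missingness. The
latent y, z never appear in the exported survey table — inference code
sees only what a real interviewer would — but are returned in a
row-aligned truth sidecar for testing.

`study_fixture` is the canonical emulation of the survey the package
reproduces: 75 clusters × 20 students, p = 0.24, covariate margins from
the study's descriptive tables (63.2% girls among respondents with
recorded sex and a 27-in-1481 missing rate for sex, 60.3% aged 18–21
spread uniformly over single years, 91.5% urban, four
religious-attendance levels, seven media-exposure categories), overall
prevalence 0.41 and an age-21-vs-18 odds ratio of 3.7 with all other
covariate effects null.

Two generator constants deserve comment:

- **Cluster SD.** The study states only "design effect = 2". σ_u = 1.12
  was calibrated once by Monte Carlo so that the empirical design effect
  of λ̂ under 75 × 20 clustering averages ≈ 2, and then frozen. A single
  75-cluster replicate estimates its own design effect with ~16% relative
  error, so per-replicate checks use a generous band.
- **Marginal truths.** With a logit random intercept this large,
  cluster-conditional and population-averaged effects differ
  (attenuation ≈ 1/√(1 + 0.346σ_u²)). The fitted regression is marginal,
  so its estimand is the population-averaged odds ratio; the fixture
  therefore declares its truths (π = 0.41, OR 3.7) on the marginal scale
  and derives the conditional intercepts per age group by Gauss–Hermite
  inversion of E[σ(η + u)]. Declaring conditional truths instead would
  make the recovery tests measure attenuation bias rather than estimator
  quality.

What the generator does *not* emulate: respondent non-compliance with the
crosswise instructions (self-protective B answers), non-ignorable
missingness, unequal cluster sizes, and any covariate–cluster
association. Passing tests therefore certify the estimators under an
honest crosswise mechanism, not robustness to lying respondents — a known
limitation of the crosswise model itself.

## Tabulation

Frequency tables use per-variable complete-case denominators (each
variable's percents are over its own non-missing total), optionally with
an explicit "No response" category, and one-decimal percents rounded half
away from zero — the convention that reproduces every self-consistent
printed percentage of the emulated study's descriptive tables. One
printed row ("decision to escape home") is inconsistent with any common
denominator and is excluded from the reproduction test. Pearson
chi-square (no continuity correction; expected counts < 5 flagged, an
empty margin raises) and the Welch two-sample t round out the descriptive
toolkit.

## Problem sizes and determinism

All randomness flows from explicit `numpy.random.default_rng` seeds; the
pipeline re-runs byte-identically from a saved flat key-value config. The
heavier validations use: 2000 replicates for interval coverage at
n = 1454; 500 fixture replicates (n = 1500 each) for odds-ratio recovery;
10⁶ respondents for the mechanism identity and forward-rate checks; 3000
replicates at n = 10⁵ for the variance-inflation Monte Carlo oracle — the
whole suite completes in well under a minute on one core.

## Known limitations

- The inversion is undefined at p = ½ and increasingly noisy near it;
  nothing in the package rescues a badly chosen design.
- Wald intervals on π̂ inherit binomial-Wald behaviour: coverage degrades
  for small n or π̂ near the clipping boundary; the Wilson-transformed
  interval is preferable there.
- The published confidence intervals of the emulated study are mutually
  inconsistent (the girls/boys/total bounds cannot all follow from one
  method); the package reproduces the three point estimates exactly and
  validates its own intervals by coverage simulation instead of matching
  those bounds.
- Cluster-level inference uses the ultimate-cluster variance or a cluster
  bootstrap; no mixed-effects crosswise model is provided.
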