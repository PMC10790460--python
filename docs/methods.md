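# Methods

## Outcomes from the schedule

A schedule is an ordered set of antigen-dose entries with due ages in
days; the default encodes Uganda's routine childhood schedule (BCG and
OPV0 at birth; DPT, OPV and PCV doses 1–3 at 6, 10 and 14 weeks; MCV1
at 9 months) and is fully overridable in the run configuration. Survey
age is in completed months, so due ages are converted with
`floor(due_days / 30.44)` and a dose is *due* when `age_months ≥
due_months`; `doses_due` also accepts a grace period in days
(default 0).

Derived outcomes per child:

- one indicator per antigen-dose (missing receipts count as not
  received; the recode count is logged),
- `zero` — no scheduled dose received. By default this applies at any
  age, and unvaccinated children under 12 months additionally carry
  `underage_zero = 1`: they are *at risk of* zero-dose status rather
  than confirmed in it, and that flag is the fair covariate in the
  zero-dose ranking model. A `strict_zero` switch instead restricts
  `zero` to children aged ≥ 12 months.
- `full` — fully immunized *for age*: every due dose received, defined
  for children under 24 months. A newborn with no due doses besides the
  birth doses it received is vacuously fully immunized.
- `complete` — the whole schedule received, defined at 24 months and
  older (the boundary child of exactly 24 months falls on the
  `complete` side).

Every child is eligible for exactly one of `full` / `complete`, so the
two outcomes partition the sample at the 24-month cut.

## Wealth index

The household socioeconomic score is the first principal component of
the standardized asset battery (correlation-matrix PCA — appropriate
when binary assets have very different prevalences). Constant columns
are dropped with a warning; an all-constant battery is an error. The
component sign is arbitrary, so the score is oriented by a declared
"privileged" asset (default: the asset with the largest absolute
loading is made to load positively). PCA is unweighted by default with
a survey-weighted option. Quintiles cut the score at cumulative-weight
fractions 0.2/0.4/0.6/0.8; a tie group lands in the quintile containing
its mid-point cumulative weight. Precomputed survey wealth quintiles
can be ingested directly through the column mapping, bypassing PCA.

## Direct-unfairness ranking

For each outcome a logistic model (maximum likelihood, survey weights
as frequency weights) regresses the outcome on:

- fair terms: age in months (continuous) *and* the outcome-specific
  not-yet-due indicator. Both enter by default; a constant term (e.g.
  the underage flag of a birth dose) is dropped automatically.
- unfair terms: dummies for region, residence, maternal education,
  socioeconomic quintile, sex and insurance, each coded against its
  declared privileged level, so coefficients read as log-odds penalties
  of less privileged situations.

One model is fitted per outcome (DPT3 ranked by predicted DPT3,
zero-dose by predicted zero-dose, ...), because the composite indices
are reported per outcome. The ranking variable is the predicted
probability; its weighted fractional rank `F` (mid-point CDF, tie
groups pooled at their mid-point, so the weighted mean of `F` is
exactly 0.5) enters all downstream metrics. Rows where an outcome is
undefined (the 24-month cut) are excluded from that outcome's model,
ranking and metrics.

The underage indicator *perfectly separates* dose outcomes by
construction — not-yet-due children cannot have received the dose — so
its coefficient diverges while its predictions behave correctly
(underage children rank at the bottom of predicted coverage). The
separation guard therefore only screens unfair dummies
(|log-odds| > 15 raises an error naming the term); fair terms are
exempt.

For adverse outcomes such as zero-dose, ranking by predicted prevalence
puts the most at-risk children at the *top* of `F`, so a positive index
means zero-dose status concentrated among children predicted most
likely to have it; the orientation is reported rather than flipped.

## Equity metrics

All moments are weighted *population* moments (no n−1 correction): the
CDF-rank construction assumes population normalization.

- `CI_W = (2/μ)·Cov(y, F)`. Undefined at μ = 0.
- `CI_E = 4·μ·CI_W`, an exact product identity on every output.
- `AEG` = weighted coverage difference between rank-quintiles 5 and 1
  (quintiles from the cumulative-weight cuts of `F`).
- Equity level `1 − |CI_W|`. Report tables round **half-up** (Decimal,
  not banker's rounding): indices to 3 decimals, coverage to 0.1%,
  equity levels to 2 decimals.
- Concentration curve: cumulative outcome share vs cumulative
  population share ordered by `F`, with tie groups aggregated to single
  vertices; with that convention the trapezoid area identity
  `CI_W = 1 − 2·area` holds to machine precision, which the tests
  exploit as an independent route to the index.

Confidence bounds. The 95% interval for a concentration index uses the
half-width `1.96·sqrt(Var(y)/n_eff)` with `n_eff = (Σw)²/Σw²`
(mode `"estimator"`, the default). A literal mode `"as_printed"`
(half-width `1.96·sqrt(Var(y))`, no sample-size term; CLI flag
`--naive-eq4`) is retained for comparability, but it ignores the sample
size and produces intervals far too wide to be useful at survey scale.
The AEG interval is `AEG ± 1.96·sqrt(s²_Q5/n_Q5 + s²_Q1/n_Q1)` with
within-quintile weighted variances and raw observation counts.

## Decomposition

Wagstaff–van Doorslaer–Watanabe-style, adapted to the logistic link:
term k contributes `(m_k·x̄_k/μ)·C_k` where `m_k` is its average
marginal effect (for a dummy, the weighted mean change in predicted
probability switching it 0→1 holding everything else; for age,
`mean(p(1−p))·β`), and `C_k` is the term's concentration index against
the *same* composite rank `F` used for the outcome's own index —
internal consistency of the ranking. The residual is `CI − Σ
contributions`; shares are signed, never clipped, and shares + residual
sum to exactly 100% by construction. When `|CI|` is below 1e−9, shares
are undefined and absolute contributions are returned instead.
Dummy-level contributions aggregate into factor groups (region,
residence, maternal education, SES, sex, insurance, age/underage);
group share = sum of member shares. The marginal-effect formulation was
chosen over an index-function linearization because it is standard for
binary outcomes and reproducible from the fitted model alone; on real
survey data, factor *ordering* is the robust output, not digit-level
share values.

## Synthetic-data generator

The generator emulates the structure of a child-level immunization
survey: categorical covariates (region, urban/rural, maternal
education, insurance, sex) with configurable level probabilities; a
latent socioeconomic factor driving both a binary asset battery
(logistic measurement model with per-asset loadings and prevalence
intercepts) and the true SES quintiles; survey weights (unit by
default, lognormal option); uniform ages 0–59 months (overridable); and
per-dose receipt drawn `Bernoulli(logistic(η))` only for due doses,
with planted per-level log-odds effects.

Two design points matter for realism:

- **Cross-dose correlation.** With doses independent given covariates,
  the joint outcomes collapse — essentially no child misses everything
  (zero-dose ≈ 0.03%) and few receive everything. Real schedules are
  strongly correlated at the child level, so η includes a child-level
  normal random intercept (`child_effect_sd`, default 2.5 log-odds)
  shared across doses. An optional `monotone_doses` flag additionally
  forces dose k of an antigen to require dose k−1.
- **Calibrated intercepts.** Default per-dose intercepts are solved
  (Brent root-finding against a Gauss–Hermite marginal) so that
  population-average coverage among due children hits per-dose targets
  (90% BCG, 74% DPT3, 80% MCV1, ...). Under the defaults the generated
  populations show ≈2% zero-dose, ≈43% fully-immunized-for-age and
  ≈40% complete — the ballpark of recent East African surveys.

`expected_stratum_coverage` is the analytic oracle: exact logistic
probabilities per covariate stratum, marginalized over the child effect
by 80-point Gauss–Hermite quadrature, independent of the seed. A fixed
config + seed reproduces the population byte-for-byte.

What the generator does **not** emulate: cluster/stratum survey design
(weights are independent of covariates, so design-effect variance is
absent); informative missingness (the optional missing-dose rate is
missing-at-random); card-vs-recall measurement error; age heaping.
Passing tests therefore demonstrate estimator correctness under known
structure, not robustness to those real-data features.

## Numerical choices

- Fractional ranks: stable sort; tie groups pooled at mid-point
  cumulative weight, preserving mean 0.5 exactly.
- Quintile of a rank `f`: `min(floor(5f)+1, 5)`.
- Weights must be strictly positive and finite; all metrics are
  invariant to a global weight rescaling and to row permutation.
- Separation threshold 15 log-odds; GLM (IRLS) defaults otherwise.
- Missing dose values recode to "not received" with a logged count
  (conservative coverage, the common survey convention); unrecognized
  raw codes without a declared default are errors, not silent drops.

## Test and verification scale

The suite verifies desk-size worked examples exactly, algebraic
identities to machine precision on an 8,000-child simulated survey,
coefficient recovery at n = 100,000 (within 3 reported SEs), null
calibration of the index and AEG over 200 populations of n = 2,000, and
single-factor recovery/attribution at n = 50,000 — sizes chosen so the
Monte-Carlo error of each check is well below the effects being
verified while the whole suite runs in well under a minute.

## Known limitations

- **In-sample ranking bias.** The composite ranking uses in-sample
  predictions, so under an exact no-inequity null the fitted ranks
  correlate with the outcome through overfitting: the bias of `CI_W` is
  O(√(k/n)) against a sampling SE of O(1/√n) — a constant ≈√k standard
  errors at *any* n for a k-term model. It is negligible relative to
  real survey indices (≈0.01 at n = 20,000 for the default model) but
  means the composite index should not be interpreted as exactly
  mean-zero under the null; null-calibration checks here use the
  fit-free wealth ranking. Cross-fitted predictions would remove the
  bias and are a natural extension.
- Variance estimation ignores survey design (no cluster-robust or
  bootstrap errors; a bootstrap flag is future work).
- The decomposition's share values depend on the marginal-effect
  convention; only factor ordering should be compared across
  implementations.
- Low-prevalence outcomes (zero-dose at ≈2%) make Wagstaff and
  Erreygers indices diverge in magnitude by construction (`CI_E =
  4μ·CI_W` with small μ); both are always reported.
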