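# Methods

## The estimand and the estimator

The package estimates the causal elasticity between two ln-scale phenotypes,
ln BMI and ln 25(OH)D, in both directions, using genetic allele scores as
instruments. Writing S for a score, X for the exposure phenotype and Y for
the outcome phenotype, the Wald/IV ratio is

    r = beta_SY / beta_SX,

where both coefficients are cohort-level OLS estimates of ln-phenotype on the
score, multiplied by 100 so they read as percent differences, and pooled
across cohorts before the division. Identification rests on the usual IV
assumptions: the score is associated with the exposure, independent of the
confounders of the exposure–outcome relation (alleles are assigned at
conception), and affects the outcome only through the exposure. Using
multi-SNP scores dilutes single-variant pleiotropy but does not test it; no
pleiotropy-robust estimators (Egger, median, mode) are provided.

The ratio's variance is the first-order Taylor (delta-method) expansion with
zero covariance between numerator and denominator:

    var(r) = se_SY^2 / beta_SX^2 + beta_SY^2 se_SX^2 / beta_SX^4.

The two pooled coefficients do come from overlapping samples, so an optional
covariance argument exists on `iv_ratio`, but the default (zero) matches the
standard ratio-variance formulation for this design. Confidence intervals and
p-values are normal-theory; a denominator with |beta|/se < 2 only flags the
result as weak rather than switching estimators, because the intended
operating regime (instrument F in the hundreds) is far from the weak limit.

Instrument strength is summarised by the approximation
F = R^2 (n - 2) / (1 - R^2), with R^2 the *marginal* squared correlation of
the score with its own ln-phenotype — the phrasing "proportion of variation
explained by the allele score" reads as marginal, and genotypes are
independent of the adjustment covariates anyway; an incremental-over-
covariates variant is available through the ``covariates`` argument of
`variance_explained`. At the collaboration level the package reports the
sample-size-weighted mean of per-cohort R^2 with the total n; this is one of
several defensible conventions and is documented here because pooled R^2 is
not uniquely defined across heterogeneous cohorts.

## Allele scores

- Weighted score (BMI): S = sum(w_i g_i) / sum(w_i) over the SNPs available
  in the cohort, g_i in {0,1,2} counting BMI-raising alleles. The rescaling
  over the sum of available weights keeps S an average dose in [0,2], which
  makes cohorts with one to three missing SNPs comparable with complete
  cohorts; missing SNPs are dropped from both sums, never imputed.
- Unweighted scores (vitamin D synthesis: DHCR7 + CYP2R1; metabolism:
  GC + CYP24A1): plain risk-allele counts of 25(OH)D-lowering alleles. A
  cohort missing any constituent SNP does not form that score at all — a
  2-SNP count with one SNP absent would change the score's meaning.

## Per-cohort regression models

ln(outcome) is regressed on the exposure plus covariates: age, sex and
principal components for every model, plus month of blood draw (categorical
indicators) when 25(OH)D is the outcome. Categorical covariates with a single
observed level (a cohort sampled in one month, a single-sex cohort) are
dropped with a warning — erroring would needlessly exclude male-only or
female-only cohorts. Rank-deficient designs raise an error naming the
collinear columns. Exact n after row-wise deletion of missing values is
carried on every estimate.

## Meta-analysis

- Fixed effects: inverse-variance weights w_i = 1/se_i^2.
- Random effects: DerSimonian–Laird moment estimator,
  tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)), re-weighting by
  1/(se_i^2 + tau^2). The DL estimator was chosen as the standard
  moment-based option for ~20-study meta-analyses; it is exact, fast and
  matches the general meta-regression machinery below with an
  intercept-only design (a property the tests exploit). A REML tau^2 is
  available behind the ``tau2_estimator="reml"`` flag.
- Model selection: random effects when Cochran's Q has p < 0.05 (strict;
  the threshold is configurable), else fixed — recorded per pooled estimate
  in the run log since only the selected model appears in the tables.
- Meta-regression: weighted least squares of study effects on a study-level
  factor, method-of-moments residual tau^2 (the multi-parameter analogue of
  DL), z-based inference. With ~21 studies the normal approximation is mildly
  anti-conservative; Knapp–Hartung small-sample inference (t on k - p df
  with the variance adjustment) sits behind a flag rather than being the
  default, to keep CIs comparable with plain normal-theory reporting.
  Categorical factors need an explicit reference level in the pipeline
  configuration.
- Multivariate (bivariate) pooling of the joint synthesis+metabolism model:
  fixed-effects GLS, pooled vector (sum C_i^-1)^-1 sum(C_i^-1 b_i) with the
  study-specific within-study covariance C_i from the joint regression, and a
  2-df Wald test for the joint null. A method-of-moments random-effects
  variant (between-study covariance = sample covariance of effects minus mean
  within-study covariance, eigenvalue-clipped to PSD) sits behind a flag.
  Studies with singular C_i are dropped with a warning.

Implementation note: the pooling, heterogeneity, meta-regression and GLS code
is written in numpy/scipy directly (cross-checked in the test suite against
frozen reference values from an independent meta-analysis implementation and
against brute-force dense solves); per-cohort regressions go through
statsmodels OLS.

## Synthetic cohort generator

Genotypes: Binomial(2, EAF) per SNP — Hardy–Weinberg and linkage equilibrium;
no LD, no imputation uncertainty, no population structure (the emitted
principal components are pure noise, present only so adjustment code runs).
Default allele frequencies are drawn uniformly from (0.2, 0.5), the
common-variant range typical of GWAS instruments.

Phenotypes follow the structural system (in deviations from cohort means)

    B* = Z_b + delta * V*,   V* = Z_v + gamma * B*,

solved in reduced form (invertible iff |gamma*delta| < 1, enforced), where
Z_b collects the BMI genetics, small age/sex effects, a shared standard
normal confounder U (loading 0.3 on both phenotypes) and N(0, 0.15^2)
residual noise, and Z_v adds the vitamin D genetics, the seasonal term and
N(0, 0.35^2) noise. Defaults: gamma = -0.42, delta = 0 — a one-directional
world in which adiposity lowers vitamin D status and the reverse effect is
absent, which is exactly the configuration whose recovery the estimator
tests target.

Seasonality is a cosine in month of blood draw, amplitude 0.15 ln-units,
peak month 7, months uniform on 1..12 (so the term is exactly mean-zero).
Only the functional form is an assumption; the analysis adjusts for month
categorically and never sees the cosine.

Score weight calibration: relative per-SNP weight magnitudes are drawn once
(uniform 0.5–1.5) and rescaled by one constant per trait axis so the marginal
score R^2 hits 0.97% (BMI score), 0.64% (synthesis) and 1.26% (metabolism)
under the default variance budget. Because the marginal R^2 is available in
closed form given the generator's variances, the constant is solved exactly
rather than searched iteratively. The solved per-allele effects land around
1–2% for BMI SNPs and 3.5–5% per allele for the vitamin D SNPs — the
magnitude range reported for these loci. The calibration assumes delta = 0;
with a nonzero reverse effect realised R^2 drifts mildly from target.

The bundled `dcardia21` scenario reproduces a 21-cohort, 42,024-subject
collaboration design: per-cohort sizes, sex mixes, age distributions,
phenotype geometric means, continent and assay labels, and the missing-SNP
patterns (five cohorts missing 1–3 BMI SNPs; one cohort unable to form the
synthesis score; one unable to form either vitamin D score). Which specific
rsids are masked is a package choice — the design only fixes the counts and
the score consequences.

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: LD between instruments, pleiotropy, assay
measurement error differences, relatedness/family structure, population
stratification, non-European frequencies, sporadic per-subject missingness,
and non-linear exposure effects. With the default positive confounder
loadings on both phenotypes the *observational* ln-ln association is biased
upward (it can even change sign relative to gamma); this is intentional — it
makes the contrast between the confounded observational estimate and the
confounding-immune IV ratio visible in tests — but it means the simulated
observational coefficient is not meant to match any published observational
value.

## Power by simulation

`iv_power` operationalises "effect per decile": an instrument score
Z ~ N(0,1) explains a configurable R^2 of a standardised ln-exposure; the
exposure is mapped to its population decile (1–10 via the normal CDF, an
exact decile assignment given the known marginal); the ln-outcome mean shifts
by `effect` log-units per decile around the mean decile 5.5 with N(0,
resid_sd^2) noise; each replicate's IV ratio (outcome-on-Z over decile-on-Z)
is tested at alpha. This reading of "per decile" is stated prominently
because the design is genuinely ambiguous; the package treats the decile rank
as the working exposure scale of the power model. Defaults: alpha 0.05,
2,000 replicates (binomial Monte Carlo SE reported), residual SD 0.35
ln-units for 25(OH)D outcomes and 0.16 for ln BMI outcomes in the default
grid at effects 0.02 and 0.01 log-units per decile.

## Numerical and reporting conventions

- 95% CIs use z = 1.959964 throughout; CI-to-SE back-conversion is
  (hi - lo) / (2 x 1.959964).
- Heterogeneity: I^2 = max(0, 100 (Q - df)/Q), clamped to [0, 100]; tau^2
  truncated at 0.
- The per-10%-exposure conversion multiplies the elasticity and its CI by 10
  (linear in the log-log approximation), matching the convention of reporting
  "percent change per 10% exposure change"; it is not exp(r ln 1.1).
- Report tables round ratios to 2 decimals preserving signed zero (-0.00
  denotes a negative point estimate that rounds to zero).
- Ties in model selection (p_Q exactly equal to the threshold) resolve to
  fixed effects.
- Determinism: one master seed feeds a SeedSequence; panel construction,
  each cohort, and each power-grid point get independent spawned streams, so
  reruns are byte-identical and adding cohorts does not perturb earlier ones.

## Problem sizes used in the checked experiments

Repeated-simulation checks (IV coverage ~95%, reverse-direction size ~5%) run
200 collaborations of 5 cohorts x 4,000 subjects under the default truth —
a scaled-down design whose per-collaboration instrument F is still ~200, so
the weak-instrument regime is not entered. Single-run checks use the full
21-cohort scenario. Calibration checks simulate one cohort of 30,000;
power-monotonicity checks use n = 40,000 with 2,000 replicates.

## Known limitations

- No individual-level two-stage least squares; everything goes through
  pooled summary coefficients (matching the intended collaboration setting
  where individual data cannot be shared).
- Delta-method CIs are symmetric and can undercover when the denominator is
  weak; the package warns but does not switch to Fieller intervals.
- The DL tau^2 and the MM meta-regression tau^2 are moment estimators;
  REML/exact-likelihood alternatives are out of scope.
- The multivariate random-effects variant uses a simple moment between-study
  covariance and should be treated as exploratory.
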