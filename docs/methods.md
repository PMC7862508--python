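# Methods

This note documents the statistical procedures the package implements, the
generative model behind the synthetic cohorts, the defaults and why they
were chosen, and what the validation suite does and does not establish.

## Score construction

Per-allele weights on the standardized exposure scale are derived from GWAS
summary statistics as `w = z / sqrt(2p(1-p)(n + z²))` with standard error
`1 / sqrt(2p(1-p)(n + z²))`; this is the closed form for a standardized
continuous trait and reduces to `z·se`-style scaling at large n. Records
reporting `beta` and `se` directly can be used as-is.

Allele alignment re-expresses weights on the cohort's effect-allele coding.
When the codings are swapped, the weight is negated and `2w` is accumulated
into an additive offset, which makes raw scores *numerically identical*
(not merely equal up to a constant) under either coding; z-scores are
therefore invariant too. Palindromic (A/T, C/G) SNPs are excluded by
default because strand cannot be resolved without frequency heuristics; an
override flag exists for data known to be strand-consistent.

Missing dosages are imputed by the expected dosage `2·p` using the weight
source's effect-allele frequency by default (`freq_source="weights"`), the
only frequency guaranteed to exist for every instrument; the cohort's own
observed frequency is available as `freq_source="cohort"`. With no
missingness the choice has no effect.

Standardization uses the analysis dataset's own mean and sample SD (ddof=1),
pooling cases and controls. Tertile grouping is rank-based with stable ties;
when n is not divisible by 3 the extra samples go to the *lower* groups
first, a fixed deterministic convention.

## Association and mediation

Binary outcomes use a binomial GLM (IRLS, tolerance 1e-8, 100 iterations
maximum; quasi-separation is detected and raised as a convergence error),
continuous outcomes use OLS. Inference on the score coefficient is Wald,
two-sided, normal; confidence intervals are `beta ± 1.96·se`. Categorical
covariates (array platform) are expanded to indicator contrasts; analysis
is complete-case with logged missingness counts.

Mediation is operationalized purely as covariate adjustment:
`pct_attenuation = 100·(1 − β_adjusted/β_base)`, flagged undefined when the
base coefficient is numerically zero. No formal mediation decomposition
(Sobel, product-of-coefficients, counterfactual) is attempted — the
quantity mirrors how adjustment results are reported in the applied
literature, and the simulator's full-mediation preset is the ground-truth
check that it behaves as intended.

## Meta-analysis

Standard inverse-variance fixed-effect pooling on the coefficient
(log-odds) scale: `w_k = 1/se_k²`, `se_pooled = 1/sqrt(Σw)`. Cochran's Q
(df = k−1) and `I² = max(0, (Q−df)/Q)·100` are computed as routine quality
diagnostics even though they are not headline outputs. No random-effects
model is provided. Fixed-effect pooling is associative (pooling a pooled
subset with the remaining cohorts equals pooling all cohorts), which the
tests exploit as an invariant.

## Two-sample Mendelian randomization

Harmonization starts from the exposure table's SNPs, flips outcome (and
second-exposure) effect signs where allele pairs are swapped, and excludes
palindromic SNPs, allele mismatches, and SNPs absent from any table, each
with a recorded reason. A warning is emitted when exposure and outcome
tables declare the same cohort tag (two-sample overlap).

- **IVW** is fixed-effect with no residual-scale inflation — the
  estimator's original form; p-values are two-sided normal.
- **MR-Egger** first orients every SNP so `bx ≥ 0` (the standard
  identification condition), then fits the weighted regression with a free
  intercept. Standard errors carry a multiplicative residual scale bounded
  below by 1; p-values use the t distribution with k−2 df.
- **Weighted median** interpolates the inverse of the cumulative normalized
  weight at 0.5; its SE is a parametric bootstrap (`bx ~ N(bx, sx)`,
  `by ~ N(by, sy)`), seed mandatory, default 1000 replicates.
- **MV-IVW** regresses `by` jointly on both exposures' effects without
  intercept (weights `1/sy²`); all-zero exposure columns are dropped
  (reducing to univariable IVW) and rank deficiency raises with the
  condition number.

The consensus rule flags a relationship reliable when at least two of the
three univariable methods give p strictly below 0.05; the reported estimate
is always IVW's. All p thresholds in the package are strict inequalities.
The sensitivity filter removes instruments whose p-value in any supplied
risk-factor table is below 1e-3 (configurable), reporting per-factor counts;
an instrument absent from a table is not excluded by it.

## The generative model

Instrument SNPs are independent (no LD), Hardy–Weinberg, with MAF uniform
on [0.05, 0.5]. Effect magnitudes are drawn from the *tail* of a normal
(|N| > 1 SD of the `weight_scale` = 0.015 distribution): published
instrument lists are the selected genome-wide-significant hits of a large
discovery scan, so near-zero effects do not occur among them.

The phenotype chain is:

1. standardized true score `G` → latent intelligence (path `g_iq`,
   default 0.22, i.e. the score explains ~5% of latent intelligence
   variance, consistent with what large intelligence GWAS report for this
   class of score);
2. latent intelligence → a discretized 0–13 test score
   (`iq_measurement_r` = 0.8 plus rounding), mimicking a short
   verbal-numeric reasoning test;
3. measured intelligence ↔ education: the bidirectional relationship is
   resolved as a per-run causal direction (`iq_to_edu` by default,
   `iq_edu` = 0.45) plus a shared genetic component (`g_edu_shared` = 0.1);
   a simultaneous cyclic model is not identifiable and is deliberately not
   attempted;
4. the *measured* mediators drive six risk-factor liabilities (BMI,
   smoking, T2D, hypertension, HDL, LDL; binary ones thresholded at their
   configured prevalences) — downstream traits depend on the measured
   variables, so adjusting for a measured mediator blocks its path exactly,
   which is the property the mediation analyses test;
5. CAD liability combines the risk-factor liabilities (coefficients 0.15 to
   0.30), small direct mediator effects (−0.08 intelligence, −0.15
   education), and residual noise; disease status is the liability-threshold
   indicator at 6% prevalence. Residual SDs keep each latent near unit
   variance (covariances between standardized parents are ignored — latents
   are approximately, not exactly, standardized).

The default path coefficients were set once so that the implied total
effect of measured intelligence on CAD liability is ≈ −0.30 per SD and of
education ≈ −0.29, and the marginal score-disease association lands near
OR 0.95 per SD — the magnitudes this kind of study reports. Principal
components are pure-noise covariates by default and array platform a random
binary label, so covariate adjustment is a no-op in truth (adjustment
correctness is tested as such). Case-control studies are simulated by
oversampling cases from a population pool at the configured sampling-frame
prevalence.

Two-sample summary statistics come in two modes. `cohort` mode runs
vectorized per-SNP marginal regressions (OLS for continuous traits,
IRLS logistic for binary) on two *disjoint* simulated samples, so exposure-
and outcome-side estimation errors are independent by construction.
`analytic` mode draws `bx_hat ~ N(bx_true, sx)`, `by_hat ~ N(by_true, sy)`
with standard GWAS standard-error approximations (continuous exposure at
n = 270,000; case-control outcome at n = 180,000 with case fraction 0.33).
Configured causal truths are `β_intelligence = −0.29` and
`β_education = −0.48` per SD. Pleiotropy adds direct SNP-to-outcome effects
(count, SD, and directional mean configurable); effect alleles are oriented
exposure-increasing, which is what makes directional pleiotropy directional
after Egger's re-orientation.

In standalone analytic mode, instrument strength is drawn directly as a
selected-hits z distribution, `z ~ 5.45 + Exponential(12)`: every
instrument is genome-wide significant and the exposure-effect measurement
error is negligible relative to the spread of true effects
(`I²_GX ≈ 0.97`). This is an *estimator-validation* regime: MR-Egger in
particular is attenuated whenever `I²_GX` drops much below ~0.97 (the NOME
assumption), and empirical instrument sets for cognitive traits sit nearer
`I²_GX ≈ 0.8` — see Limitations. When summary statistics are generated to
match a simulated cohort (`truth=...` or `cohort` mode), per-allele effects
instead follow the cohort's DAG chain exactly.

## Named presets

- `tiny` — 10 SNPs × 60 samples; end-to-end smoke material.
- `default` — 242 SNPs × 5000 samples under the full DAG, with matched
  two-exposure summary statistics.
- `mediation-null` — full mediation (score → measured intelligence →
  disease, path −0.6, no direct or risk-factor paths), balanced
  case-control at n = 20,000 with sampling-frame prevalence 0.2, score
  path `g_iq` = 0.3. Sized by a pre-hoc power calculation: the base
  log-OR (≈ −0.24) must exceed 5 times the slope SE (≈ 0.015) for the
  80%-attenuation check to be stable.
- `pleiotropic` — 48 of 242 instruments (20%) carry directional pleiotropy
  (mean 0.01, SD 0.01), the regime where the weighted median outperforms
  IVW.

## Validation strategy

The test suite checks four kinds of property: exact oracle agreement
(IVW against no-intercept weighted least squares, fixed-effect pooling
against its closed form and statsmodels' implementation, the tertile
contrast against the 2×2 cross-product OR); parameter recovery (mean
estimates of all MR methods within Monte-Carlo error of configured truths
over 200 replicates); statistical calibration (uniform p-values under the
all-null DAG; Egger intercept type-I error at nominal level); and
behavioural orderings (weighted median beating IVW under 20% invalid
instruments; >80% attenuation under full mediation). Mechanical rules —
the 7-SNP overlap exclusion leaving 235 of 242 instruments, the strict
2-of-3 consensus, tertile sizes differing by at most one, the sensitivity
filter removing exactly the constructed-to-fail SNPs — are asserted
directly.

Problem sizes in the suite (cohorts of 600 for calibration, 20,000 for
mediation, 200–500 replicates) were chosen as the smallest at which the
checked quantities are statistically stable.

What passing does **not** show: the simulator omits LD between instruments,
imputation uncertainty, relatedness, population stratification (unless the
optional two-population mode is used), winner's-curse bias in instrument
effects, and real measurement artefacts; agreement with the generative
truths here does not imply the same accuracy on real cohort data.

## Known limitations

- MR-Egger is consistent here because the analytic mode operates at
  `I²_GX ≈ 0.97`; at realistic instrument strength for cognitive traits
  Egger attenuates toward the null and would need SIMEX-style correction,
  which is out of scope.
- The liability-threshold/logistic correspondence is first-order: logistic
  coefficients on simulated case-control data are liability-consistent odds
  ratios, not equal to the liability path coefficients.
- Binary risk factors mediate through their underlying liabilities, not
  their observed 0/1 states.
- The weighted-median bootstrap resamples summary statistics parametrically;
  with very few instruments (< ~10) its SE is optimistic.
- `exactly one of {beta+se, z+eaf+n}` is enforced per table on read;
  tables mixing the two schemes row-wise are validated row-wise but must
  satisfy one scheme per row.
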