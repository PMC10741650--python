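# Methods

This note documents the statistical procedures implemented in
`mrmediate`, the defaults and why they were chosen, what the synthetic
data generator does and does not emulate, and the numerical conventions.

## Instrument selection and harmonisation

Candidate instruments for each exposure are filtered in a fixed order —
genome-wide significance, user-supplied confounder exclusion list,
instrument strength, LD independence — and each removal is logged once
with the first matching reason, so QC is auditable and order-independent
in outcome.

* **p-threshold** (default `5e-10`) and **LD r² threshold** (default
  `1e-4`): these defaults reproduce the thresholds of the
  platelet-index–stroke study this package reimplements, which are
  stricter than the conventional 5e-8 / r² < 0.001. Both are exposed in
  `QCConfig`; users analysing other data will often want the
  conventional values.
* **F statistic** `(β/se)²` with cutoff 10, the standard
  weak-instrument screen.
* **Confounder screening** is an explicit exclusion list rather than an
  online database lookup; the seven blood-lipid-associated rsIDs used in
  the motivating study ship as
  `mrmediate.sumstats.LIPID_ASSOCIATED_SNPS`.
* **LD pruning** is greedy on a user-supplied pairwise r² table:
  variants are visited in ascending p-value order (ties broken by
  variant ID for determinism) and dropped when correlated above
  threshold with an already-kept variant. Pairs absent from the table
  are treated as independent — no reference panel is downloaded. The
  simulator generates unlinked variants, so the estimator suite is fully
  testable offline.

Harmonisation expresses every trait's effect for the exposure's effect
allele: swapped alleles negate the effect and reflect the frequency;
strand flips are resolved by A↔T / C↔G complementation before matching.
Palindromic (A/T, C/G) variants cannot be strand-resolved by allele
labels, so orientation falls back on allele frequency; when the
frequency lies within `palindromic_eaf_window` (default 0.08) of 0.5 in
*any* trait the variant is dropped as ambiguous — the conservative
two-sided variant of standard practice (the window itself is a
documented convention, not part of the original study's reported
pipeline). Irreconcilable allele pairs and duplicate IDs are dropped and
logged, never silently fixed.

## Univariable estimators

* **IVW**: weighted mean of Wald ratios, weights `(βˣ/seʸ)²` (the NOME
  approximation — exposure-side noise is ignored in the weights, which
  is accurate at the F > 100 typical of the instruments simulated here).
  Fixed-effect SE is `1/sqrt(Σw)`; the default mode multiplies it by
  `sqrt(Q/(n−1))` whenever that exceeds 1 (multiplicative random
  effects). Both modes are always reported by the pipeline: the data the
  study design targets showed heterogeneity for some exposures, and the
  multiplicative model preserves point-estimate comparability with the
  fixed-effect fit.
* **Wald ratio** SE uses the first-order delta approximation
  `seʸ/|βˣ|` by default; a `second_order` flag adds the exposure term
  `βʸ²·seˣ²/βˣ⁴`. First-order is standard and conservative given large
  instrument F.
* **MR-Egger** orients all exposure effects non-negative, then fits a
  weighted regression with free intercept (statsmodels WLS). SEs follow
  the multiplicative random-effects rule
  `se = sqrt(max(1, σ̂²)·diag((XᵀWX)⁻¹))` — residual underdispersion is
  not allowed to shrink them — and p-values use the t distribution with
  n − 2 df. The intercept estimates average directional pleiotropy.
* **Weighted median** interpolates the inverse-variance-weighted
  empirical quantile function at 0.5; the SE is a seeded parametric
  bootstrap (both exposure and outcome effects redrawn from their normal
  sampling distributions, weights recomputed per draw, default 1000
  draws; below 100 a warning is emitted).
* **Cochran's Q** at a reference slope, χ² with n − 1 df; at the
  fixed-effect IVW slope it equals the weighted residual sum of squares
  of the through-origin fit (asserted in the tests).
* **MR-PRESSO-style outlier test**: each instrument's
  variance-standardised squared deviation from its leave-one-out IVW fit
  is compared against seeded parametric simulations under the
  no-pleiotropy model (default 1000; exposure and outcome effects both
  redrawn, the leave-one-out fit recomputed within each simulation). The
  sum gives an empirical global p; per-instrument empirical p-values are
  Bonferroni-adjusted over instruments and flagged below 0.05. A
  corrected IVW estimate with outliers removed is reported alongside —
  never silently substituted for the primary estimate — and the seed is
  part of the result object.
* **Steiger test**: variance explained per trait is summed over
  instruments via the t-statistic transform `r²ⱼ = tⱼ²/(tⱼ² + n − 2)`,
  which needs no allele-frequency or case-fraction information and
  therefore works unchanged for the binary outcome (no liability-scale
  correction is applied; the comparison of the two r² values is what
  drives the direction call). The p-value uses the Fisher-z comparison
  of the two correlations for independent samples, appropriate for
  non-overlapping GWAS cohorts. The pipeline runs the test before
  reporting and flags failing pairs "possible reverse causation" rather
  than dropping them.

## Multivariable MR and mediation

`mvmr_ivw` regresses outcome effects on the K exposure-effect columns
through the origin with weights `1/seʸ²`, solving the weighted normal
equations directly; per-coefficient SEs apply the same multiplicative
overdispersion rule with df n − K. A rank-deficient design raises a
collinearity error naming the most correlated column pair; a solvable
but ill-conditioned design (condition number above 30) emits a warning —
this is exactly the situation of jointly modelling systolic and
diastolic blood pressure, whose genetic effects are strongly correlated,
and the warning surfaces why their individual direct effects become
unstable in the joint model.

The mediation decomposition multiplies A (univariable MR of exposure on
mediator) by B (the mediator coefficient from the MVMR) and divides by
the total effect C; the difference method (C − C′)/C is reported as a
cross-check. Cross-consortium covariances among A, B and C are taken as
zero — the standard assumption when the three contrasts come from
non-overlapping samples. A zero total effect flags the proportion
undefined rather than raising.

The proportion's CI defaults to a seeded parametric bootstrap (draw A, B
and C independently from their normal sampling distributions, recompute
the proportion, take the 2.5/97.5 percentiles; default 10⁴ draws): the
ratio of estimates is poorly approximated by a normal when C is not far
from zero, and the bootstrap also yields the asymmetric intervals the
quantity calls for. The delta method (treating A, B, C as uncorrelated)
is provided as a fast cross-check and agrees with the bootstrap to ~10%
interval width when |C|/se_C ≳ 5. When the bootstrap's C draws change
sign in more than 1% of draws the interval is flagged unstable.

## The synthetic-data generator

`simulate_study` emulates the summary-data landscape of a two-step
mediation MR study with three non-overlapping cohorts. Structural truth
per variant j (exposure effect γⱼ, mediator-specific effect δⱼ):
mediator effect `A·γⱼ + δⱼ`, outcome effect
`C′·γⱼ + B·(A·γⱼ + δⱼ) + pleiotropyⱼ`, so valid exposure instruments
carry total effect C = C′ + A·B and mediated share
`mediated_fraction`. Defaults are the conditions of the motivating
study: 86 exposure instruments (the plateletcrit count), GWAS sizes
350,474 / 757,601 / 40,585 cases + 406,111 controls, C = 0.107
(= ln 1.113) with 28% mediated, and A = 0.570 (= ln 1.769, the
exposure→diastolic-pressure estimate; the implied B ≈ 0.053 then sits
close to the published diastolic-pressure→stroke log-odds of 0.05).

Design choices worth knowing:

* **Mediator-specific instruments** (default 95, the blood-pressure
  instrument count) are generated with γ = 0 and their own effects δ.
  They are essential: with exposure instruments alone the MVMR design's
  signal columns are proportional (mediator column = A × exposure
  column), B is unidentifiable, and two-step mediation cannot work —
  just as the real analysis unions the exposure's and the mediator's
  instruments.
* **Instrument strength**: per-variant variance explained is drawn
  uniformly from `exposure_r2_range` (default 2–8 × 10⁻⁴, sign random,
  zero-mean overall), i.e. association z-scores of roughly 8–17 at the
  default sample sizes — GWAS-scale instruments that comfortably clear
  p < 5e-10 and F ≥ 10, so the configured instrument count is what the
  pipeline actually retains. Mean F increases monotonically with the
  exposure sample size.
* **Sampling noise**: observed beta = true beta + N(0, se) with
  `se = 1/sqrt(2·maf·(1−maf)·n)` (standardised traits); binary outcomes
  use the effective sample size `4/(1/cases + 1/controls)` and effects
  are generated directly on the log-odds scale rather than through a
  liability threshold — simpler, and sufficient for estimator testing.
* **Pleiotropy**: an `invalid_fraction` of the exposure instruments
  receives a direct outcome effect drawn N(0, `pleiotropy_sd`);
  everything else is a valid instrument.
* Variants are simulated **unlinked** (the post-clumping state the
  estimators assume) with non-complementary allele pairs, so the
  harmonisation path is exercised without strand ambiguity. Tables
  regenerate bit-identically from (config, seed).

What the generator does *not* emulate — and what passing tests therefore
do not establish about real data: LD between instruments, winner's-curse
selection bias (true effects are drawn above the significance boundary
rather than selected post hoc), sample overlap between cohorts,
population structure, liability-scale binary traits, and
frequency-dependent genetic architecture. Conclusions about estimator
behaviour under those features need real summary statistics.

## Replicated-simulation experiments

`mrmediate.experiments` runs the full simulate → QC → harmonise →
estimate path over seeded replicates (sub-seeds spawned from one master
seed, all below 2³¹): IVW CI coverage (1000 replicates at the default
study conditions; observed ≈ 95–96%), Cochran's Q size under the null
(2000 replicates, 50 instruments; observed ≈ 0.05), mediated-proportion
recovery (200 replicates per true value in {0, 0.25, 0.5}; the mean
estimate lands within 0.005–0.015 of the truth — recovery is judged on
the mean across replicates, since a single replicate's proportion
inherits the full sampling noise of Ĉ and B̂), and planted-outlier
detection (one instrument's ratio displaced by 10 combined SDs among 20
clean ones; flagged in ≈ 100% of replicates). These problem sizes keep
the whole experiment suite under a minute on one CPU while leaving
Monte-Carlo error well inside the margins being asserted.

## Numerical conventions

* 95% CIs use the factor 1.96 throughout and odds ratios are
  `exp(beta)`; report tables render ORs and CIs to 3 decimals.
* P-values are two-sided and floored at the smallest positive double so
  they remain in (0, 1]; family-wise significance uses
  `alpha_family/n_tests` (default 0.05/5 = 0.01), with 0.01–0.05
  labelled "potentially significant".
* Exact-fit degeneracies (zero residual variance in Egger/MVMR, zero
  bootstrap SEs) return point-mass results rather than NaNs.
* QC and estimators are invariant to instrument reordering and to
  simultaneous sign flips of an instrument's exposure and outcome
  effects; seeds are explicit arguments everywhere randomness enters
  (weighted-median bootstrap, MR-PRESSO simulations, proportion
  bootstrap, simulator), so identical configs produce byte-identical
  report bundles.
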