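# Methods

`sibgwas` implements within-sibship genome-wide association analysis and the
inference chain built on its summary statistics, together with a synthetic
family-cohort generator used to validate every estimator against known truth.

## The two association models

For individual *j* in sibship *i* (sibships of at least two genotyped,
phenotyped full siblings), with genotype allele count G_ij in {0, 1, 2}:

* **population model**: `y_ij ~ G_ij + sex + age + PC1..PC20`
* **within-sibship model**: `y_ij ~ G^C_ij + G^F_i + sex + age + PC1..PC20`

where `G^F_i = mean_j G_ij` over the siblings present in the study and
`G^C_ij = G_ij - G^F_i`. Because the deviation `G^C` depends only on
segregation at meiosis given the parental genotypes, its coefficient is an
estimate of the direct genetic effect, free of confounding transmitted through
the family: assortative mating, population stratification, and parental
indirect genetic effects all load on `G^F`. Sibling indirect effects are not
removed (a known limitation of the design).

Both models are fitted on identical samples. A sibship in which fewer than two
members have an observed phenotype contributes no within-family contrast, so
its remaining phenotype value is set missing before either model is fitted
(`apply_missingness_rule`). Variant QC keeps MAF > 0.01 and INFO >= 0.3;
simulated data carry INFO = 1.

**Standard errors.** Both estimators cluster over sibships using the CR0
sandwich with a G/(G-1) small-sample factor (G = number of sibships); at the
thousands of clusters typical here, finer small-sample corrections are
immaterial. P-values use the normal approximation of beta/SE, consistent with
the downstream use of Z scores. An unclustered (`se_type="naive"`) option
exists for diagnostics; naive SEs are anti-conservative in family data.
Cryptic relatedness *between* sibships (e.g. cousin sibships sharing an
environment) still inflates population-model significance, while the
within-sibship contrasts remain independent across families — the simulator
reproduces this and the tests verify it by type-I error.

**Implementation.** Fits are closed-form and vectorised: phenotype and
genotype terms are residualised on the covariates once
(Frisch–Waugh–Lovell), then per-variant slopes and cluster sandwiches are
accumulated in chunks. This is algebraically identical to per-variant OLS;
the test suite checks equality against `statsmodels` (coefficients to 1e-8,
clustered SEs to 1e-6) on a small cohort. Variants with no genotype variance
(or no within-family variance, for the within model) are emitted as flagged
null records rather than dropped, keeping tables alignable across models.

## Meta-analysis and effective sample size

Per-study estimates are standardised by the cohort phenotype SD (Z scores are
invariant) and combined by fixed-effects inverse-variance meta-analysis after
allele harmonisation (swap + sign flip; unresolvable alleles dropped and
logged; strand-ambiguous variants are retained by default because simulated
data carry no strand uncertainty — `drop_ambiguous` exists for real data).

The effective sample size implied by a GWAS standard error,

    Effective N = (1 / se^2) * sd_resid^2 / (2 * MAF * (1 - MAF)),

inverts the OLS variance identity; family clustering and within-family
centering reduce it below the raw N, which is exactly why it (not raw N) is
passed to LD score regression. The study-level summary is the median of
per-variant values over MAF in [0.1, 0.4] (low-frequency variants make the
per-variant values noisy; the median is robust to the remainder).

## Weighted scores and shrinkage

For M independent discovery-selected variants with discovery weights w_k and
target estimates (beta_k, sigma_k):

    S = sum(w_k beta_k / sigma_k^2) / sum(w_k^2 / sigma_k^2),
    sigma_S = sqrt(1 / sum(w_k^2 / sigma_k^2)),

the no-intercept WLS slope of beta on w. Shrinkage is delta = 1 - S_W / S_P,
reported in percent. Its SE comes from a leave-one-variant-out jackknife,
se = sqrt((M-1)/M * sum_k (delta_k - mean)^2), because the two scores come
from separately fitted models with unknown covariance; a delta-method SE with
a user-supplied covariance is also exposed (positive covariance shrinks the
SE). Instruments are selected from an *independent* discovery sample by greedy
LD clumping (ascending p; r^2 < 0.001 within 10 Mb; thresholds 1e-5 primary,
5e-8 sensitivity); a provenance label check refuses weights whose source
matches the target sample, guarding against winner's curse. A population
score with |Z| < 2 flags the ratio as unstable rather than erroring.

**Heterogeneity of shrinkage across variants.** Per-variant Wald ratios
s_k = beta_P,k / beta_W,k are tested for homogeneity with Cochran's Q against
the precision-weighted combined ratio. The variance of each ratio uses the
delta method including the second-order denominator term,

    var(s_k) = (sigma_P,k^2 + S^2 sigma_W,k^2) / beta_W,k^2
               * (1 + 3 (sigma_W,k^2/beta_W,k^2)
                      * (sigma_P,k^2 + 3 S^2 sigma_W,k^2)
                      / (sigma_P,k^2 + S^2 sigma_W,k^2)),

with variants at |Z_W| <= 2 removed first (weak denominators make ratios
explode). The first-order form is noticeably anti-conservative at moderate
instrument strength; with the second-order term the test holds its nominal
5% level for strong instruments (|Z_W| ~ 20+, the regime of top hits in a
large meta-analysis) and is conservative below that — the safe direction for
a homogeneity claim. Cohort-level heterogeneity of per-study shrinkage
estimates uses the standard inverse-variance Cochran Q.

## LD score regression (minimal)

Model: E[chi2_j] = N h2 l_j / M + N a + 1, so a weighted regression of chi2
on the LD score l_j gives h2 = slope * M / N, an intercept 1 + N a capturing
confounding, and the ratio (intercept - 1)/(mean chi2 - 1) as the confounded
share of inflation (clipped to [0, 1] with a flag — sampling noise makes
small excursions routine; undefined when mean chi2 <= 1). N is the effective
sample size. Weights are 1/max(l_j, 1) with one reweighting pass by the fitted
mean squared; weights are estimated once on the full data and held fixed
across jackknife blocks. SEs come from a delete-one block jackknife over 100
contiguous blocks in (chromosome, position) order (reduced with a warning on
small panels); the block solves reuse per-block normal-equation sums, so the
jackknife costs O(M + B). Full LDSC weighting, MHC defaults and partitioned
models are intentionally out of scope.

Cross-trait: E[z1 z2] = sqrt(N1 N2) rg sqrt(h2_1 h2_2) l_j / M + overlap
intercept; rg = gencov / sqrt(h2_1 h2_2), undefined (flagged) when either h2
is non-positive at numerical tolerance. Difference tests:

* h2: difference-of-two-means with Cov = Cor * se_Pop * se_WS, where Cor is
  the cross-GWAS intercept (sampling overlap between the population and
  within-sibship GWAS of the same trait);
* rg: 100-block jackknife of r_g,Pop - r_g,WS recomputed per left-out block.

Uniform shrinkage multiplies Z by (1 - k), so the expected within-sibship
heritability is h2_WS = (1 - k)^2 h2_Pop (`expected_ws_h2`); with the
published education values (h2_Pop = 0.13, k = 0.47) this gives 0.0365,
consistent with the published within-sibship estimate of 0.04.

## Mendelian randomization

Fixed-effect IVW with first-order weights:

    beta_MR = sum(beta_Exp beta_Out / se_Out^2) / sum(beta_Exp^2 / se_Out^2),
    se = sqrt(1 / sum(beta_Exp^2 / se_Out^2)),

equal to the no-intercept WLS slope of beta_Out on beta_Exp (M = 1 reduces to
the Wald ratio). Exposure SEs are ignored in the weights, matching the
estimator as defined; Cochran's Q across Wald ratios is logged as an
overdispersion diagnostic rather than inflating the SE. Population and
within-sibship MR estimates are compared with a leave-one-variant-out
jackknife on the difference.

## Polygenic adaptation (tSDS)

Raw SDS are normalised to mean 0, SD 1 within each 1% derived-allele-frequency
bin — bins are half-open [k/100, (k+1)/100) with the last bin closed, and
bins with fewer than 2 variants pass through flagged. Regions under strong
recent selection are excluded first (MHC chr6:25,892,529–33,436,144; lactase
chr2:134,608,646–138,608,646; 1-based inclusive). After merging with GWAS
results, variants with effective N strictly below 50% of the maximum are
removed (exactly 50% is retained), and SDS are signed to the trait-increasing
allele (tSDS; beta exactly 0 is flagged, not dropped). The test statistic is
Spearman's rank correlation between tSDS and |Z| with an SE from a 100-block
genomic jackknife; the p-value uses the jackknife Z statistic, matching the
SE machinery rather than the classical Spearman test.

## The synthetic cohort generator

The generator produces exactly the structures the estimators are meant to
separate, with truth tables for recovery tests:

* **Mendelian transmission** — each child allele drawn independently and
  uniformly from the parent's two alleles. Under random mating the sib-sib
  genotype correlation is 0.5; under mate genotype correlation r it is
  (1 + r)/(2 + r).
* **Assortative mating** — single-generation: mothers are rank-matched to
  fathers on phenotype plus matching noise with variance var(y)(1/r^2 - 1),
  hitting a target cross-mate phenotypic correlation of r (within ±0.05 at
  5,000+ couples). Multi-generation equilibrium assortment is out of scope.
* **Stratification** — two balanced subpopulations with per-variant allele
  frequency divergence ±Δp/2 (random sign) and a phenotype mean offset.
  Simulated PCs are the subpopulation indicator plus leakage noise
  (`pc_leakage_sd`), so tests can represent PCs that only partially absorb
  structure; `pcs_from_genotypes=True` computes true genotype PCs instead.
* **Indirect genetic effects** — per causal variant, eta_parental per
  parental allele and eta_sibling per sibling allele enter the phenotype
  additively. Under random mating cov(G_child, G_m + G_f)/var(G_child) = 1,
  so the population slope converges to beta + eta_parental while the
  within-sibship slope converges to beta; equal beta and eta give a true
  shrinkage of 0.5.
* **Shared environment and cryptic relatedness** — a per-sibship normal
  shared-environment term; with probability `cryptic_relatedness_frac`, two
  sibships share a parent-generation founder couple (their mothers are drawn
  as full siblings) and share the environment draw, creating the
  cross-sibship correlation that clustering over sibships cannot absorb.
* **Phenotype scale** — the residual noise variance tops the systematic
  variance up to 1, so effects stay on the phenotype-SD scale without
  rescaling; realized component vectors are stored for exact variance
  decomposition. If systematic variance exceeds 1, no noise is added.

Summary statistics for the LD score regression stages are generated directly
under the chi2 model above (`simulate_ldsc_summary` / `simulate_ldsc_pair`
with correlated genetic and noise components); the cohort simulator carries
no linkage disequilibrium (realistic LD simulation is out of scope), so
LDSC is not identified from the cohort GWAS itself. Synthetic SDS tables are
standard normal within frequency strata, with an optional shift aligning the
derived allele of large-effect variants with recent selection.

All randomness flows from one integer seed through named
`numpy.random.SeedSequence` substreams (`variants`, `parents`, `matching`,
`cryptic`, `children`, `covariates`, `phenotype`, `ldsc`, `sds`), so cohorts,
scenarios and reports are bit-reproducible.

### What the generator does not emulate

Real LD and imputation error; multi-generation assortment at equilibrium;
non-linear or gene–environment effects; phenotype measurement heterogeneity
across cohorts; the X chromosome. Passing tests therefore demonstrate that
the estimators behave as derived under the stated generative model, not that
any particular real-data estimate is reproduced.

## Problem sizes and numerical choices

Validation experiments use desk-scale sizes chosen to keep Monte-Carlo error
well inside the asserted bands: estimator separation at 20,000 sibling pairs
and 60 causal variants; null calibration at 3,000 sibships × 6,000 null
variants (binomial SE ≈ 0.003 on a 5% rate); jackknife-fidelity comparisons
at 300 replicates (relative SE ≈ 4% on an SD); LDSC recovery at M = 20,000
over 100 seeds. Degenerate inputs (monomorphic variants, singleton sibships,
constant rank inputs, empty instrument sets, non-positive heritability) are
flagged or raised explicitly rather than silently propagated; ties in ranks
use average ranks; genomic coordinates are 1-based inclusive throughout.
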