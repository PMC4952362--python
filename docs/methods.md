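# Methods

This note documents the statistical procedures the package implements, the
assumptions behind the synthetic cohorts it tests itself on, and the
numerical and design choices made where the method description left the
design open.

## cis-eQTL mapping

For each gene the cis window is the annotated gene span extended
symmetrically by `cis_radius_bp` (default 100,000 bp), strand-ignored and
clamped at position 1. Within the window, SNPs with minor allele frequency
≥ `maf_min` (default 0.05, computed on the analysed samples of the cell
type after missing-data removal) are tested.

The test is Rao's score test for adding allele dosage to a Gaussian linear
model of normalized expression on covariates. With covariate design X
(intercept always included), annihilator M = I − X(XᵀX)⁻¹Xᵀ, null
residuals e = My and null ML variance σ̂₀² = eᵀe/n, the statistic for
dosage g is (gᵀe)²/(σ̂₀²·gᵀMg), distributed as χ²₁ under the null and
identical to n times the squared partial correlation of expression and
genotype given the covariates. p values are the χ²₁ upper tail. The
statistic is invariant to affine rescaling of expression.

**Permutation FDR.** The null is built by permuting genotype sample labels
(`n_perms_eqtl` = 320 times) against fixed expression/covariate pairs;
permuting the genotype side rather than expression preserves the
expression–covariate association under the null, so confounder structure
survives. All (gene, SNP) pairs of a cell type form one test family; FDR
at observed p value t is the pooled plug-in estimate

    FDR(t) = min(1, (#{permuted p ≤ t}/n_perms) / max(#{observed p ≤ t}, 1)),

monotonized so FDR is non-decreasing in t (q(t) = min over t′ ≥ t), with
significance declared at FDR < 0.10. The alternative of estimating FDR on
per-gene best statistics rather than all pairs would be more conservative
per gene; the all-pairs family maximizes discovery for downstream set
construction, which is the purpose of the mapping stage.

**Missing dosages.** The scalar score test removes samples with missing
genotype pairwise. The vectorised mapper instead drops samples missing at
*any* cis SNP of a gene (listwise within gene): per-SNP sample sets that
change under permutation would defeat the vectorised permutation stream.
The synthetic cohorts contain no missing calls, so both rules coincide on
everything the tests measure.

**Best SNP per gene/cell type** is the minimum-p row, ties broken by
larger χ² then lexicographically smaller SNP id. The gene × cell-type
matrix of −log₁₀(FDR) floors FDR at 1/n_perms before the logarithm
(the plug-in estimate can be exactly 0, which is simply "below the
permutation resolution").

**Subgroup concordance.** For each significant eQTL, expression is
regressed on dosage within patients and controls separately (ordinary
least squares, keeping the non-group covariates); the paired slopes and
standard errors are emitted plot-ready. Monomorphic-within-group SNPs are
reported with a reason instead of a slope.

**Exhaustive variable selection.** At loci with several significant SNPs,
all 2^k subsets (k ≤ 10; larger loci are truncated to the 10 most
significant SNPs first) of the candidate dosages are fitted with the
covariates always retained, and the subset minimizing the Bayesian
information criterion is reported; ties go to the smaller subset, then the
lexicographically smaller id tuple, making duplicated SNPs resolve
deterministically. BIC was chosen because it is consistent for fixed k and
deterministic; AIC and adjusted R² are available as options. The empty
subset (covariate-only model) is a legal winner.

## LD and the eQTL SNP set

LD between two SNPs is the squared Pearson correlation of dosage vectors
(composite LD; no phasing is assumed). Tagging collects all SNPs within
1 Mbp of an index SNP at r² ≥ `r2_tag_min` (default 0.8, inclusive; an
absolute slack of 1e-12 keeps thresholds that are not binary-representable
inclusive in floating point).

**Relative independence.** Candidates are scanned greedily in a supplied
order — by convention descending index-eQTL significance for set
construction, genomic position for the genome-wide background (a
significance ordering would bias the background λ upward). A candidate is
retained iff its multiple correlation coefficient (square root of R² from
regressing its dosage on all previously retained dosages, intercept
included) is ≤ `max_multiple_corr` (default 0.33). Because a greedy pass
alone cannot guarantee that *earlier* retained SNPs still satisfy the
ceiling against everything retained afterwards, a joint audit follows:
R_i for each retained SNP against all the others is computed from the
inverse correlation matrix (R_i² = 1 − 1/(C⁻¹)ᵢᵢ) and, while any exceeds
the ceiling, the latest-ordered violator is dropped. The audit table
records every candidate with its multiple R and a removal reason
(`greedy` vs `joint_audit`), so runs are fully auditable. The filter is
implemented with an incrementally updated orthonormal basis, making it
O(n·K·k) rather than one least-squares solve per candidate.

**Set construction** proceeds: restrict to significant best-eQTL rows →
drop genes overlapping the configured MHC region (default
chr6:25,000,000–34,000,000; genes there may appear disease-associated only
through long-range LD with strong MHC signals) → tag each index SNP →
intersect proxies with the cohort's genotyped SNPs → independence-filter.
A proxy shared by several genes enters the set once but keeps every
provenance row, so gene-level analysis still sees it under each source
gene. An empty result at any step raises an error naming the eliminating
step.

## Disease association

The allelic test is Pearson's χ² (1 df, no continuity correction; a Yates
flag exists for sensitivity analyses) on the 2×2 table of REF/ALT allele
counts in cases versus controls, invariant to allele relabelling. SNPs
with a zero allele-count margin are dropped with a log entry.

The self-contained set statistic is the sum of per-SNP allelic χ² over the
set. Phenotype labels are permuted `n_perms_set` (default 10,000) times
with genotypes untouched, preserving inter-SNP LD; the empirical p is the
fraction of permuted sums strictly greater than the observed sum. Ties
count as not greater, so p can be exactly 0; results carry both the raw
fraction and a `p_reported` string that renders 0 as `<1/n_perms`, and a
conservative (b+1)/(B+1) variant is available. Gene-level analysis applies
the same machinery per source gene (each gene's proxies independently
pruned at ≤ 0.33) with **one shared permutation stream** across genes —
a single permuted dataset serves every gene, preserving the inter-gene
correlation of the null and halving compute — followed by
Benjamini–Hochberg adjustment across genes. Genes whose proxies do not
survive genotyping/pruning are reported as missing with a reason.

Inflation is the median-based genomic-control factor λ =
median(χ²)/0.4549364231 (the χ²₁ median). λ for the genome-wide background
is computed on position-ordered, independence-filtered SNPs. λ₁₀₀₀
rescales the set λ to an equivalent 1000/1000 cohort:
λ₁₀₀₀ = 1 + (λ−1)·((1/n_cases + 1/n_controls)/(1/1000 + 1/1000)); it is
affine in λ with fixed point 1, and the identity λ₁₀₀₀ = λ holds at
1000/1000. qq tables pair sorted observed χ² with χ²₁ quantiles at
(i − 0.5)/n.

Risk-allele expression directions re-orient each eQTL slope (per ALT
allele) to the cohort's risk allele — the allele at higher frequency in
cases — and classify it as increasing or decreasing expression; the
classification is invariant under simultaneous allele relabelling and
slope sign flip. Catalog enrichment of gene-set loci is a two-sided
Fisher's exact test on the hits-vs-background 2×2 table, returned with the
sample odds ratio.

## Chromatin-mark analysis

Coverage tracks are interval lists with counts (1-based inclusive
internally; BED's 0-based half-open intervals are converted at the
boundary, and overlapping intervals sum on query). Coverage at a SNP is
the summed count of intervals overlapping the SNP's single base, scaled to
counts per million by the track total; "intersecting" is deliberately the
minimal 1-bp reading, with a `window_bp` widening knob since a
region-overlap reading is equally defensible.

Enrichment compares the observed mean CPM over the eQTL SNPs with
`n_iter_null` (default 10,000) random draws of the same number of SNPs,
without replacement, from the full cis-region SNP pool. The one-sided
empirical p counts null means above the observed with exact ties at half
weight: for continuous coverage this equals the plain "fraction at or
above" rule almost surely, while on heavily tied discrete tracks it keeps
the null p uniform and gives the degenerate draw (eQTL set = whole pool)
its natural p of 0.5. An LD-expanded variant repeats the comparison with
the eQTL SNPs replaced by eQTL SNPs plus all their r² ≥ 0.8 proxies.
eQTL strength versus acetylation is Spearman's ρ between per-gene best
χ² (regardless of significance) and CPM at those SNPs.

## Synthetic cohorts

The generator produces exactly the statistical structure the analysis
assumes, no more:

- **Genotypes.** Haplotypes follow a copying chain within blocks of
  `ld_block_size` SNPs: each allele copies its left neighbour with
  probability `ld_rho` or is drawn fresh at that SNP's frequency
  (frequencies uniform on `maf_range`, default 0.10–0.45). Marginal
  frequencies remain convex combinations of in-range values; r between
  neighbours ≈ ld_rho and decays along the chain, which is all the
  analysis needs — realistic LD *magnitudes*, not realistic haplotype
  genealogies (a coalescent simulator would add nothing testable here).
  SNP coordinates are laid out so each gene's ±radius cis window contains
  exactly `snps_per_gene_region` SNPs and windows of adjacent genes do not
  overlap.
- **Expression** = 5 + Σ covariate effects + β·dosage + N(0, noise_sd),
  per cell type, with β taken from the scenario's planted eQTL map
  (default noise_sd 1, in normalized-expression units; Gaussian noise
  matches the score test's model). Covariates: status ~ Bern(0.4),
  sex ~ Bern(0.5), age ~ U(20, 70), batch ~ Bern(0.5).
- **Case-control cohorts.** Disease probability is
  logit⁻¹(α + Σ log(OR)·dosage) with α solved by bisection so the expected
  case fraction matches n_cases/(n_cases+n_controls); individuals are
  drawn from the genotype pool (regenerated with fresh seeds when
  exhausted, bounded at 200 regenerations) until exactly n_cases cases and
  n_controls controls accrue, giving fixed cohort sizes for λ₁₀₀₀.
- **Coverage.** Exactly `library_size` reads of 100 bp; with peaks
  configured, half the reads centre on peak SNPs with Gaussian (σ = 60 bp)
  offsets, the rest land uniformly over the SNP-covered span.

What the generator does **not** emulate — microarray probe effects,
population structure, imputation uncertainty, genotyping missingness and
batch-specific technical noise — bounds what passing tests show: they
validate the statistical machinery (calibration, recovery, invariances,
determinism) under the model's own assumptions, not robustness to the
artefacts of any particular real platform.

## Numerical choices and determinism

- One global seed; stage seeds derive from it by fixed offsets, and every
  stochastic step uses `numpy.random.default_rng` on a derived seed. A
  re-run of the same configuration is byte-identical (result tables are
  written with a fixed `%.10g` float format and `\n` line endings).
- Inclusive thresholds (r² ≥ 0.8, multiple R ≤ 0.33) carry an absolute
  1e-12 slack so binary-unrepresentable constants behave inclusively.
- Best-subset ties are resolved within a relative 1e-9 BIC tolerance by
  subset size then lexicographic ids; RSS is floored at 1e-300 before the
  logarithm.
- Degenerate inputs raise informative errors rather than returning
  sentinels: monomorphic genotypes (score test, LD), zero-margin allele
  tables, constant vectors (Spearman), empty candidate sets (set
  construction names the eliminating step), zero-total coverage tracks.
- Exact-0 permutation p values are reported as such (with the `<1/n_perms`
  string alongside) rather than silently replaced by the conservative
  variant.

## Problem sizes used by the shipped scenario and checks

The built-in demonstration scenario uses 30 genes × 10 cis SNPs, 150
expression samples in four cell subsets, 320 eQTL permutations, a
1000/1000 cohort with 10,000 phenotype permutations and 10,000 resampling
iterations — large enough for every stage to be exercised meaningfully and
small enough that the full pipeline runs in seconds on one CPU. The
calibration checks in the test suite use 200 genes × 5 SNPs at n = 200 for
FDR calibration (planted β = 0.46, sized analytically for ≈ 0.8 power at
the effective per-test α), 200 null cohorts of 500/500 for the set test's
type-I error, and a 1200-SNP background with a 200-SNP set (5 % causal,
OR 2.0, 1000/1000) for λ sensitivity — sizes chosen so the median-based λ
statistics have enough resolution for the comparisons being asserted.

## Known limitations

- The permutation-FDR family is all pairs per cell type; per-gene-best
  FDR is documented but not implemented.
- The independence filter's greedy-plus-audit scheme is one deterministic
  resolution of an under-specified criterion; clumping-style or
  iterative-removal variants would retain different (equally defensible)
  sets.
- The allelic set test carries no covariate adjustment, logistic score
  tests are out of scope, and the gene-set test is self-contained only
  (no competitive variant).
- Cis windows ignore strand, and the build string of input files is
  carried through, not validated.
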