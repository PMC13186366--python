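# Methods

## Scope and model

colocgap implements the single-causal-variant colocalisation workflow used
by large GWAS–eQTL screens, end to end: harmonisation and standardisation of
summary statistics, eGene selection, per-region Wakefield-ABF fine-mapping
with a cross-trait coverage gate, five-hypothesis colocalisation posteriors,
an FDR-calibrated PP(H4) threshold, aggregation of tests to independent GWAS
peaks, regression analyses of colocalisation determinants and study-design
enrichment, and the multi-gene (co-regulation) analyses. Everything runs on
synthetic inputs with exported generative truth; no external data are
required.

The single-causal-variant assumption is load-bearing throughout: per-variant
log ABFs combine additively into hypothesis-level evidence only because at
most one variant per trait is causal in a region. Multi-causal fine-mapping
(e.g. SuSiE-style decompositions) is deliberately out of scope.

## Summary-statistics handling

Variants are matched across datasets by (chromosome, position); when ref/alt
are swapped the effect sign is flipped. Strand-ambiguous (A/T, C/G) variants
are retained and matched on allele set by default — their mis-orientation
cannot be detected without frequency comparison, which we do not model — and
a flag drops them. Summary statistics are 1-based inclusive; all interval
arithmetic (enhancer overlap) is 0-based half-open internally.

For quantitative traits the trait variance is estimated from the summary
statistics themselves: with v_i = 2 n_i f_i (1−f_i) and w_i = 1/SE_i²,
sdY² = Σ v_i w_i / Σ w_i², the no-intercept least-squares slope of v_i on
w_i. This is the standard identity SE_i² ≈ sdY²/v_i rearranged as a
regression, robust to a handful of outlying standard errors. Effects and
standard errors are then divided by sdY (the SD, not the variance): dividing
by the SD maps the trait to unit variance so β is comparable across studies
while z-scores and p-values are unchanged; the exponent is exposed as a
config option for sensitivity analysis.

eGenes are selected per study by Bonferroni-correcting each gene's minimum
eQTL p-value by its SNP count (capped at 1) and applying Benjamini–Hochberg
across genes at FDR < 1%.

## Fine-mapping, QC and colocalisation

Effect-size prior SDs default to 0.15 for quantitative traits and 0.2 (log
odds) for case-control traits, the convention of the single-causal-variant
ABF framework. Fine-mapping posteriors are computed on each dataset's full
regional variant set *before* restriction to the shared set — this is the
only ordering under which the coverage statistics q1, q2 can fall below 1 —
and the test proceeds only if min(q1, q2) > 0.9 (strict). Coverage is summed
by genomic position, since posterior mass is invariant to allele
orientation.

All hypothesis evidence is combined in log space (log-sum-exp throughout; no
raw exponentials of unshifted log ABFs, stable across ±700 log units). The
H3 term log(e^{S1+S2} − e^{S12}) is clamped to −∞ when S1+S2 ≤ S12 within a
1e-12 guard: with one shared variant, or perfectly concentrated signals,
PP(H3) is a structural zero.

### FDR calibration

If PP(H4) is calibrated, the expected FDR among tests with PP(H4) > α is
mean(1 − PP(H4)) over that set. Candidate thresholds are the observed unique
PP(H4) values (the estimator is a step function changing only there); α is
the smallest candidate with estimated FDR below the target, evaluated on the
strict exceedance set. When no test strictly exceeds a candidate the closed
set {PP(H4) ≥ α} is used for that candidate, so a test set of perfect
posteriors calibrates to their common value while a set of uninformative
ones is reported as uncalibratable (α = None) rather than silently passed.
Significance calls use strict exceedance: PP(H4) > α.

## Peaks

Credible-set lead variants merge into peaks by single-linkage chaining of
leads < 30 kb apart per trait and chromosome (strict inequality); the
chain's representative is the smallest-p member with a position tie-break,
making the operation deterministic, idempotent and input-order invariant.
Tests are assigned to the candidate peaks whose lead falls in the test's
±1 Mb window. A significant test with several candidates goes to the peak
whose lead carries the largest GWAS fine-mapping posterior within the shared
set (fallback: the peak lead nearest the variant maximising labf1+labf2) — a
deterministic, reproducible stand-in for manual inspection of multi-peak
regions that encodes the same intent: which peak drives the colocalisation.
Non-significant tests with several candidates are assigned to all of them,
since colocalisation was rejected against each. Peak-level colocalisation
rates carry 95% Wilson score intervals.

## Regression analyses

All per-test regressions share one inference convention: maximum-likelihood
logistic (or linear) fits with cluster-robust sandwich standard errors
aggregated within peaks. The implementation (statsmodels `cov_type=
"cluster"`) applies the G/(G−1)·(n−1)/(n−k) finite-sample factor, which
reduces to G/(G−1) for n ≫ k; with singleton clusters it coincides with
heteroskedasticity-robust errors up to that factor.

Lead-variant determinants: MAF, log10 GWAS p, log10 distance (kb) to the
nearest TSS with distances floored at 1 bp before the log (a zero distance
is otherwise undefined; the floor maps an on-TSS lead to −3), and a 0/1
active-enhancer overlap.

Cell-type enrichment follows the grouped design: indicators per non-reference
group plus a per-group test-count covariate (log10 by default, for scale
stability; the raw count is an option). Because the count is group-constant
it is *always* aliased with the indicators plus intercept; we enter it,
detect the rank deficiency, and drop the aliased column with a warning —
the same outcome an R glm reports as an NA coefficient. P-values are
Bonferroni-adjusted by the number of non-reference groups. The study-design
model (granularity, composition, stimulation, with cell-type indicators and
whole blood excluded) uses baselines NK / sorted / controls / resting;
single-levelled factors are dropped with a warning. Perfect separation is
detected from fitted probabilities pinned at 0/1 and flags estimates
unreliable instead of failing.

## Multi-gene analyses

The peak-gene matrix (one row per peak × gene × study test) drives:

- **Randomisation null.** Study order is permuted (default 100 iterations)
  and the cumulative mean over peaks of distinct significant genes is
  traced as studies accrue, on observed data and after permuting PP(H4)
  uniformly within each peak with significance re-called at the *fixed*
  calibrated α (not re-calibrated per permutation — the null targets the
  call rule actually used). Concentrated real signals fall below the
  permuted curve; random false positives would match it.
- **Threshold sensitivity.** Counts of peaks with ≥1/2/3 colocalising genes
  over a PP(H4) grid; monotonically non-increasing by construction.
- **Cross-mappability filter.** Counts are symmetrised by pairwise max;
  within each peak, while any retained significant gene pair has a positive
  count, the involved gene with the lowest maximum PP(H4) is excluded
  (ties: lexicographically larger id first). Keeping the stronger signal is
  a choice the upstream analyses leave open; this one is deterministic and
  never touches peaks with fewer than two significant genes.
- **Control pairs.** Per (peak, gene) the max-PP(H4) test is pre-selected;
  each significant gene pair yields one control pair by randomly selecting
  one member and pairing it with a non-significant gene tested at the same
  peak in the *non-selected* member's cell type, sampling controls without
  replacement; pairs without an eligible control are dropped and reported,
  keeping case and control counts equal.
- **Co-regulation contrast.** Squared Pearson correlation of log(x+1)
  expression per pair, then linear models of r² (and separately of TSS
  distance) on the case indicator with peak-clustered errors. Pairs with
  constant expression (undefined correlation; detected as zero range) are
  dropped and counted.
- **Enhancer links.** Links with E2G score > 0.164 are active; analysis is
  restricted to peaks whose lead sits inside an active enhancer, the
  outcome being whether that enhancer is linked to the test's eGene in the
  test's cell type. Proportions are stratified by the number of significant
  genes per peak, top-coded at 3, and a random-intercept (peak) logistic
  model with significance, stratum and their interaction as fixed effects
  is fitted by variational Bayes (statsmodels `BinomialBayesMixedGLM`);
  effect direction and magnitude are read from the posterior mean/SD.

## Synthetic data

The generator emulates the statistical structure the analyses assume, not
human genetics in full:

- **LD panels.** A latent Gaussian AR(1) chain with per-step autocorrelation
  decay^(distance in kb) (default decay 0.98, i.e. adjacent-variant
  correlation ≈ 0.82 at 10 kb) is thresholded at per-variant target allele
  frequencies (uniform in [0.05, 0.5] by default) to produce binary
  haplotypes whose r² decays with physical distance. Diploid genotypes are
  sums of two haplotypes drawn with replacement.
- **Summary statistics.** Phenotype = genotype·β + unit-variance Gaussian
  noise (scaled by a configurable trait SD); case-control traits use a
  liability threshold at configurable prevalence, with effects analytically
  controlled, and per-variant allelic 2×2 log odds ratios with Haldane
  correction. Marginal per-variant regressions — not joint fits — produce
  beta/SE/p, matching what real GWAS/eQTL pipelines emit. H4 shares one
  causal variant, H3 draws a second causal with r² < 0.05 to the first.
- **Study panels.** Defaults are desk-scale: one GWAS trait, 4–6 regions
  3 Mb apart, 60 variants per region, 400 haplotypes, GWAS n = 4,000
  (β = 0.35), eQTL study sizes 400–2,000 (β = 0.6), three genes per region.
  The default study list spans whole blood/bulk through sorted and
  single-cell designs with cell types recurring across designs, so design
  covariates remain identifiable next to cell-type indicators. Per-study
  colocalisation is Bernoulli with a base probability (0.3) scaled by
  configurable per-cell-type multipliers; non-colocalising genes carry an
  independent eQTL with probability 0.5 (H3 negatives) or none (H1).
  Co-regulated gene pairs (rate 0.3) share a latent expression factor with
  loading √0.6 (pair correlation ≈ 0.6) and co-colocalise with probability
  0.9. Enhancer links follow the generative probabilities 0.4 (significant
  gene) vs 0.03 (non-significant), with each region's enhancer always
  linked to at least one distal gene outside the tested set so that peak
  selection does not condition on the tested genes' links.
  Note that these defaults are chosen to give the tiny panel enough
  positives to exercise every analysis: with ~27 tests per peak at a 0.3
  base rate, nearly every peak ends up with at least one colocalisation,
  so desk-scale peak-level rates saturate near 1 — unlike real screens,
  where per-test rates of a few percent leave peak-level rates well below
  1. Lower `base_coloc_prob` to emulate the sparse regime.
- **Seeding.** One integer seed feeds a numpy SeedSequence; per-region and
  global streams are spawned from it, so reruns are reproducible and
  module-level experiments can be replayed in isolation.

What the generator does **not** model: realistic human LD (no recombination
hotspots or coalescent structure), population stratification, imputation
noise, allele-frequency mismatch between studies, multi-allelic sites, or
expression count noise (expression is log-normal). Passing tests therefore
demonstrate correctness and calibration of the *procedures* under their own
assumptions, not performance on real cohorts.

## Problem sizes and numerical choices

The calibration experiment uses 2,000 regions of 30 variants (300
haplotypes, n = 1,500 per trait, effect sizes uniform on [0.1, 0.4], 60%
H3 / 40% H4) — sizes chosen so each region is individually well-powered
while the experiment spans weak and strong signals; the empirical FDR at
the calibrated α lands near 0.02 against the 5% target. Enrichment
recovery uses 250 peaks × 6 studies × 3 genes per replicate with a true
cell-type odds ratio of 2. Oracle-equivalence checks run 200 random regions
of ≤ 10 variants against exhaustive configuration enumeration at 1e-10;
posterior normalisation is property-tested at 1e-10 (coloc) and 1e-12
(fine-mapping) over inputs spanning ±700 log units.

Degenerate inputs are handled explicitly rather than by exception where the
statistics are defined: single-variant regions (PP(H3) = 0), empty
exceedance sets in calibration (closed-set fallback), monomorphic variants
(undefined r², reported as missing), constant covariates and aliased
designs (dropped with warnings), separation (flagged unreliable).

## Known limitations

Harmonisation is per-position biallelic only; multi-allelic sites are
dropped. The coverage gate shares one prior SD per trait type; a per-trait
gate prior is a one-line config change. The variational GLMM understates
posterior SDs relative to full Laplace/quadrature fits — we use it for
effect direction and approximate magnitude, not for sharp inference. The
FDR calibration assumes PP(H4) is (close to) calibrated; under model
misspecification (e.g. multiple causal variants) the estimated FDR can be
optimistic, which is precisely why the empirical-FDR check against
generative truth is part of the test suite.
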