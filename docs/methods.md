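# Methods

This note documents the models, estimators and numerical choices behind
`haqtl`, what the synthetic cohort generator does and does not emulate, and
the limitations a user should keep in mind.

## ARE activity model and quantification

Activity of ARE *i* in sample *k* is the summed fragment overlap divided by
ARE length, `Activity_{i,k} = Σ_j overlap(Frag_{j,k}, ARE_i) / length_i`,
with BED-style 0-based half-open coordinates throughout. Inputs are already
fragment intervals; read-to-fragment extension, duplicate marking and peak
calling are upstream of this package. Depth normalization is
median-of-ratios: per sample, the median over all-positive ARE rows of the
ratio to the row's geometric mean, with factors rescaled to geometric
mean 1. The median is taken on the ratio scale (the stated estimator); for
odd row counts this coincides with the log-scale median some
implementations use, and the test suite cross-checks against pydeseq2 on an
odd-count instance. GC correction is a deliberately simple quantile-bin
median equalization (default 10 bins, off by default): within each GC bin,
each sample is rescaled so its bin median matches the pooled bin median.
It removes monotone GC artifacts but is not a full-covariate GC model.

Candidate peak filtering keeps a peak iff (q ≤ 0.01 and ≥ 1 bp overlap with
peaks from ≥ 2 Tier-1 samples) or it overlaps a tissue-matched reference
peak; reference rescue deliberately ignores the q-value (the rescue rule is
about cross-dataset support, not caller confidence). A surviving peak must
then overlap a promoter/enhancer chromatin-state interval by ≥ 50 bp.
"Presence in a sample" is ≥ 1 bp overlap between peak calls.

## ARE modules and groups

The signal matrix (−log10 p scale in real data; activity in synthetic mode)
is binarized at cutoff 2 with "≥" at the boundary. AREs are clustered by a
Lloyd-style k-centroids algorithm under the generalized Jaccard distance
`1 − Σ min(x, c) / Σ max(x, c)` with real-valued mean centroids. Because
the mean is not the exact minimizer of summed Jaccard distance, each
centroid update is acceptance-tested (kept only if it does not increase
the cluster's cost), which makes the objective provably non-increasing and
guarantees termination; ties in assignment break to the lowest module
index, and the best of `n_restarts` seeded initializations is kept.
Real-mode defaults are 141 modules (~2,000 AREs each) and ~200 AREs per
submodule; synthetic tests use small k. Sample clustering is average-linkage
hierarchical clustering on 1 − Pearson distance (default 11 clusters in
real mode). Group assignment: ubiquitous score = fraction of samples with
module-mean activity ≥ 0.2; score > 0.5 → broadly-active, 0.1 < score ≤ 0.5
→ multitissue, all-zero activity → newly-detected, otherwise the sample
cluster with the strongest mean signal. Boundary scores fall to the lower
category ("above 0.5" is strict).

## cis-haQTL mapping

Phenotypes are residualized once against an intercept, known covariates and
the top principal components of the phenotype matrix (PCs stand in for
PEER-style latent factors; real-mode default factor counts 5/5/10/2 for the
four tissues, 2 in synthetic mode), then scanned variant-by-variant with
simple regression — orders of magnitude faster than per-variant
multiple regression and standard practice. Degrees of freedom are reduced by
the number of removed design columns. The cis window is ±100 kb from the
ARE center; variants need empirical MAF ≥ 0.05. Only autosomal features are
intended; the synthetic genome is a single autosome.

Locus-level multiplicity is handled by permutation: the phenotype vector is
permuted across samples (default 1,000 permutations), the minimum nominal p
over window variants recorded per permutation, and a Beta(a, b) fitted to
the minima by maximum likelihood (scipy MLE with method-of-moments
fallback; shapes clamped to [10⁻³, 10⁶]). The empirical p is the Beta CDF
at the observed lead p; the direct estimate (r+1)/(n+1) is reported
alongside, and the Beta-approximated value is used downstream when they
disagree. Features with empirical p ≤ 0.005 are gAREs; their haQTLs are
window variants with nominal p below the inverse Beta CDF of 0.005. Lead
ties break by smallest p, then smallest |distance to center|, then variant
id. Permutations are vectorized as a correlation between the permuted
phenotype matrix and unit-normalized dosages, which is exact because all
window variants share the same degrees of freedom.

## Tissue sharing

For lead haQTLs significant in a discovery tissue, replication-tissue
statistics are attached where the ARE is present and the variant typed;
pairs are binned by replication p at (10⁻⁵, 10⁻³, 0.1) and directionality
consistency DC (fraction of sign-concordant pairs) computed per bin. The
sharing proportion is `Σ_i Perc_i (2 DC_i − 1)`: a bin of fully concordant
pairs contributes its mass, a bin at chance (DC = 0.5) contributes nothing.
Pairs with an exactly zero effect are dropped with a warning (sign
undefined); DC is unweighted by precision, as specified. The raw signed
value is kept for diagnostics and clamped to [0, 1] for reporting. Type-I
(haQTL-shared) calls require replication p ≤ 0.02 in at least one other
tissue; ARE absence from every other tissue gives type III. Note the
estimator is conditional on discovery: in the synthetic cohort, effects
based in the replication tissue and copied into the discovery tissue are
shared with certainty, so the conditional sharing among discovered leads
exceeds the unconditional planted sharing probability — both are exposed in
the simulation truth.

## Colocalization

Per-variant log approximate Bayes factors follow the Wakefield asymptotic
form `0.5·log(1 − r) + 0.5·z²·r`, `r = W/(V + W)`, with V the squared
standard error and prior effect variance W = prior_sd². Defaults:
prior_sd 0.15 for quantitative traits (standardized phenotype scale), 0.2
for case-control on the log-odds scale; hypothesis priors p1 = p2 = 10⁻⁴,
p12 = 10⁻⁵ (field-standard single-causal-variant defaults). Posteriors over
H0–H4 are accumulated in log space with logsumexp; the H3 cross-term uses a
stable log-difference, so loci with |z| up to 50 over 10⁴ variants stay
finite. GWAS–haQTL loci with PP4 ≥ 0.5 are colocalized; colocalized loci
whose best GWAS–eQTL PP4 is below 0.1 are bulk-eQTL-missing. Multi-causal
colocalization and LD-aware fine-mapping are out of scope.

## gLink scores

Candidate pairs are gAREs 2 kb–1 Mb from a gene TSS, distance measured to
the nearer ARE boundary (matching the "proximal" reading of distance
scores). The six scores: (1) minimum distance from the gene's fine-mapped
eQTLs to the ARE interval (∞ sentinel when none; proximal ≤ 2 kb); (2)
best nominal eQTL p within 2 kb of the ARE; (3) coloc PP4 of the haQTL and
eQTL signals; (4) PP4/PP3, capped at 10⁶ when PP3 underflows; (5) the MR
Wald ratio β_eQTL/β_haQTL at the lead haQTL instrument, first-order
delta-method standard error, two-sided normal p, BH-adjusted across pairs,
significant at adjusted p < 0.2 (inverse-variance weighting over multiple
instruments is available behind a flag); (6) Pearson correlation between
ARE activity and polygenic-score-predicted expression Σ weight·dosage. The
unified score is the mean of oriented percentile ranks (distances and
p-values inverted so larger = stronger), missing components ignored — the
original study defers its aggregation formula to supplementary material, so
a transparent rank mean was adopted and left configurable. Enrichment of
GWAS-colocalized gAREs among linked gAREs uses a one-sided two-sample
proportion z-test against the all-gARE background.

## Synthetic cohort generator

Genotypes: per LD block, two latent AR(1) Gaussian haplotypes per
individual thresholded at each variant's allele-frequency quantile —
Hardy–Weinberg dosages with controllable within-block LD (`ld_rho`,
default 0.6, block size 20) and independent blocks. Allele frequencies are
uniform on `maf_range` (default 0.05–0.5); variants sit on a uniform grid
(default 2 kb spacing) on one synthetic autosome. Activity is
linear-Gaussian: `β·dosage + covariates·loadings + N(0, noise_sd)`,
matching the additive model the QTL regression assumes — the study's
count-level noise is exercised only through the fragment simulator, which
inverts the activity formula with Poisson fragment counts placed uniformly
inside each ARE. Each ARE gets one causal variant within 25 kb of its
center (cis effects concentrate near their targets) and a base tissue;
effects are copied across tissues with the probabilities in
`sharing_matrix`, with identical β (hence identical sign). The first
covariate mimics a broad cell-fraction confounder (loadings centered at
0.5), motivating latent-factor removal. Genes pair with AREs spread across
the panel; a `frac_shared_causal` fraction of pairs reuses the ARE's causal
variant (these are the true links), the rest draw a distinct variant near
the TSS. GWAS z-scores are drawn from N(Rλ, R) with R the empirical dosage
correlation, non-centrality `causal_z` at a configurable fraction of haQTL
causal variants, and one effect sign per 200 kb neighbourhood so nearby
causal variants reinforce rather than cancel; standard errors follow
1/√(2·MAF·(1−MAF)·n) for a standardized trait.

What the generator does **not** emulate: read-level artifacts (duplicates,
GC bias, input controls), population structure and admixture, non-Gaussian
activity distributions, multiple independent causal variants per locus, and
trans effects. Passing tests therefore demonstrate correctness of the
estimators under the additive single-causal-variant model, not robustness
to those real-data complications.

## Validation scale and numerical choices

The validation suite and `scripts/acceptance.py` use desk-scale instances
chosen to give stable measurements: 200 null features at n = 100 with 50
variants and 1,000 permutations for calibration (10,000 permutations on 50
loci for the Beta-vs-direct comparison); 200 loci for effect recovery;
10 × 1,000 lead pairs per planted sharing level; 100 loci of 200 variants
with |z| = 8 causal signal for colocalization; a 400 × 40 four-block matrix
for clustering; and a 200-individual, 400-ARE, 200-gene cohort for the
linking chain. Effect-size recovery is reported as the mean estimate across
loci (an unbiasedness check): the per-locus OLS sampling sd at n = 100 and
unit noise is ~0.15, so per-locus absolute error is dominated by sampling
noise, not estimator bias. MR sign agreement is evaluated on the MR calls
the method reports (adjusted p < 0.2): below that threshold the Wald
estimate is noise-dominated and its sign carries no information.

Degenerate inputs are handled explicitly: constant phenotypes, rank-
deficient designs (collinear columns are named), empty cis windows (empty
result, not an error), zero-variance polygenic scores, empty variant
intersections in coloc, all-zero ARE rows in normalization (error
suggesting a pseudo-count), and both-empty vectors in the Jaccard distance
(distance 0).

## Known limitations

- The permutation scheme permutes the phenotype vector, which assumes
  exchangeable samples; kinship or population structure would require
  permutation within strata or a mixed model.
- The Beta fit can be poor when the window holds a single variant or when
  permutation minima pile up at 1; shapes are clamped and the direct
  estimate is always reported for comparison.
- Coloc assumes at most one causal variant per trait per locus; violations
  inflate PP3 at loci with allelic series.
- The unified gLink score is a rank aggregate; scores are comparable only
  within the candidate set they were ranked in.
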