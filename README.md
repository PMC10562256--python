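# haqtl

Histone-acetylation QTL mapping and regulatory-element–gene linking for
multitissue H3K27ac cohorts.

## What this package does

Bulk H3K27ac ChIP–seq across many individuals and tissues lets you treat the
activity of each active regulatory element (ARE — an H3K27ac-marked
promoter or enhancer interval) as a quantitative trait and map the genetic
variants that control it (haQTLs). `haqtl` implements that analysis chain as
a tested, reusable library plus CLI, for epigenomics groups who have
per-sample fragment intervals, peak calls, genotype dosages and (optionally)
eQTL and GWAS summary statistics:

1. **ARE quantification** — candidate-peak filtering (q ≤ 0.01, ≥ 2 Tier-1
   samples or reference rescue, ≥ 50 bp chromatin-state overlap),
   cross-tissue reference merging, fragment-overlap activity
   `Activity_{i,k} = Σ_j overlap(Frag_{j,k}, ARE_i) / length_i`, and
   median-of-ratios (DESeq2-style) depth normalization.
2. **ARE modules** — binarize the signal matrix (cutoff 2), cluster AREs by
   k-centroids under the Jaccard distance, and assign modules to named
   groups (broadly-active if ubiquitous score > 0.5, multitissue if in
   (0.1, 0.5], newly-detected if silent everywhere, otherwise the strongest
   sample cluster).
3. **cis-haQTL mapping** — residualize on covariates plus latent factors
   (top phenotype PCs), scan a ±100 kb window (MAF ≥ 0.05), and compute a
   locus-level empirical p by permutation with a Beta-distribution fit to
   the per-permutation minimum p. AREs with empirical p ≤ 0.005 are gAREs
   (genetically influenced AREs); per-locus nominal thresholds give their
   haQTL lists.
4. **Tissue sharing** — pair discovery-tissue lead haQTLs with their
   replication-tissue statistics, bin by replication p (10⁻⁵, 10⁻³, 0.1),
   measure directionality consistency DC per bin, and estimate
   `Tissue-sharing = Σ_i Perc_i · (2·DC_i − 1)`; gAREs are classified as
   type I (haQTL-shared, replication p ≤ 0.02), II (haQTL-specific) or III
   (ARE-specific).
5. **Colocalization** — Wakefield approximate Bayes factors and PP0–PP4
   posteriors over single-causal-variant configurations; GWAS–haQTL loci
   with PP4 ≥ 0.5 are colocalized, and colocalized loci with no gene
   reaching GWAS–eQTL PP4 ≥ 0.1 are bulk-eQTL-missing.
6. **gLink scores** — six genetic ARE–gene linking scores for candidate
   pairs 2 kb–1 Mb from the gene TSS (distance to fine-mapped eQTLs,
   best proximal-eQTL p, coloc PP4, PP4/PP3, Mendelian-randomization Wald
   ratio with BH-adjusted p < 0.2, and the correlation between ARE activity
   and polygenic-score-predicted expression), aggregated into a unified
   percentile-rank score, plus a one-sided proportion test for enrichment
   of GWAS-colocalized gAREs among predicted links.

Real cohort data of this kind are access-controlled, so the package ships a
first-class synthetic cohort generator (`haqtl.synthetic`) producing
genotypes with blockwise LD, activities with planted cis effects and
configurable cross-tissue sharing, expression with planted eQTLs that can
share causal variants with haQTLs, fragments, and GWAS summaries with
planted colocalization — every downstream stage is testable against known
ground truth.

## Worked example

Map haQTLs in two simulated tissues and estimate cross-tissue sharing:

```python
import pandas as pd
from haqtl.synthetic import SimConfig, simulate_cohort
from haqtl.qtl import map_qtls
from haqtl.sharing import pair_leads, consistency_by_bin, sharing_proportion

cfg = SimConfig(n_individuals_per_tissue={"brain": 100, "heart": 100},
                n_variants=500, n_ares=100, n_genes=30, seed=42)
cohort = simulate_cohort(cfg)
centers = pd.Series(cohort.ares["center"].to_numpy(), index=cohort.ares["are_id"])

results = {}
for t in ("brain", "heart"):
    loci, qset = map_qtls(cohort.activity[t], centers, cohort.genotypes[t],
                          cohort.covariates[t], n_latent_factors=2,
                          n_permutations=1000, seed=1)
    results[t] = (loci, qset)
    print(f"{t}: {len(qset.features)} gAREs of {len(loci)} AREs "
          f"(empirical p <= 0.005)")

loci_b, qset_b = results["brain"]
leads = pd.DataFrame({
    "feature_id": qset_b.features,
    "variant_id": [qset_b.loci[f].lead["variant_id"] for f in qset_b.features],
    "beta": [qset_b.loci[f].lead["beta"] for f in qset_b.features],
    "p_nominal": [qset_b.loci[f].lead["p_nominal"] for f in qset_b.features],
})
rep = pd.concat([lr.nominals for lr in results["heart"][0]], ignore_index=True)
pairs = pair_leads(leads, rep, discovery_tissue="brain", replication_tissue="heart")
est = sharing_proportion(consistency_by_bin(pairs), "brain", "heart")
print(f"brain->heart tissue sharing: {est.sharing:.2f} ({len(pairs)} lead pairs)")
```

Output:

```
brain: 26 gAREs of 100 AREs (empirical p <= 0.005)
heart: 27 gAREs of 100 AREs (empirical p <= 0.005)
brain->heart tissue sharing: 0.85 (26 lead pairs)
```

26 of 100 AREs reach locus-level significance in brain (each ARE carries a
planted effect of random size, so only the stronger ones are detectable at
n = 100). The sharing estimate 0.85 is the directionality-consistency
estimate of the fraction of discovered brain lead haQTLs whose effect is
also active in heart; in this cohort 77% of the discovered brain gAREs truly
carry a planted heart effect, and the estimate agrees within the sampling
error of 26 pairs.

The same chain runs from the shell:

```bash
haqtl run-all --seed 5 --outdir out/           # full synthetic pipeline
haqtl simulate --seed 5 --outdir cohort/       # or stage by stage
haqtl validate --dosages cohort/dosages_t1.tsv --bed cohort/ares.bed
```

`run-all` writes per-stage TSV/BED/JSON outputs and a `manifest.json` with
content hashes; reruns with the same seed are byte-identical.

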