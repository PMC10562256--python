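"""End-to-end pipeline orchestration over a single declarative config.

Stage order: synthetic (or real) ingest -> fragment quantification and
normalization -> module clustering -> per-tissue cis-QTL mapping ->
tissue sharing -> colocalization (haQTL x GWAS, eQTL x GWAS,
haQTL x eQTL) -> gLink scoring -> enrichment report.  Each stage writes
its outputs (TSV/BED/JSON) before the next starts and is recorded in a
run manifest with content hashes, so deterministic stages can be
verified byte-for-byte across reruns.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coloc as coloc_mod
from . import glink as glink_mod
from . import io as hio
from . import modules as modules_mod
from . import qtl as qtl_mod
from . import quant as quant_mod
from . import sharing as sharing_mod
from . import synthetic as synth_mod

logger = logging.getLogger("haqtl")

__all__ = ["PipelineConfig", "validate_inputs", "run_pipeline", "glink_score_table"]


@dataclass
class PipelineConfig:
    """Declarative pipeline configuration (YAML-loadable)."""

    outdir: str = "haqtl_out"
    seed: int = 0
    tissues: dict[str, int] = field(default_factory=lambda: {"t1": 60, "t2": 60})
    # synthetic cohort
    n_variants: int = 300
    n_ares: int = 300
    n_genes: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 20
    ld_rho: float = 0.6
    haqtl_effect_sd: float = 0.8
    eqtl_effect_sd: float = 0.8
    noise_sd: float = 1.0
    sharing_prob: float = 0.5
    frac_shared_causal: float = 0.5
    covariate_count: int = 2
    gwas_shared_fraction: float = 0.5
    # quantification demo
    quant_samples: int = 4
    mean_depth: float = 20.0
    fragment_length: int = 200
    # module clustering
    binarize_cutoff: float = 2.0
    n_modules: int = 8
    n_restarts: int = 3
    n_sample_clusters: int = 4
    activity_threshold: float = 0.2
    # QTL mapping
    window_bp: int = 100_000
    maf_min: float = 0.05
    n_permutations: int = 1_000
    n_latent_factors: int = 2
    empirical_threshold: float = 0.005
    # sharing / coloc / glink thresholds (study defaults)
    p_share_threshold: float = 0.02
    pp4_colocalized: float = 0.5
    pp4_eqtl_missing: float = 0.1
    link_quantile: float = 0.9

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        if isinstance(cfg.maf_range, list):
            cfg.maf_range = tuple(cfg.maf_range)
        return cfg

    def sim_config(self) -> synth_mod.SimConfig:
        t = list(self.tissues)
        m = np.full((len(t), len(t)), self.sharing_prob)
        np.fill_diagonal(m, 1.0)
        return synth_mod.SimConfig(
            n_individuals_per_tissue=dict(self.tissues),
            n_variants=self.n_variants,
            n_ares=self.n_ares,
            n_genes=self.n_genes,
            maf_range=tuple(self.maf_range),
            ld_block_size=self.ld_block_size,
            ld_rho=self.ld_rho,
            haqtl_effect_sd=self.haqtl_effect_sd,
            eqtl_effect_sd=self.eqtl_effect_sd,
            noise_sd=self.noise_sd,
            sharing_matrix=pd.DataFrame(m, index=t, columns=t),
            frac_shared_causal=self.frac_shared_causal,
            covariate_count=self.covariate_count,
            seed=self.seed,
        )


def validate_inputs(
    dosage_paths: dict[str, str | Path] | None = None,
    bed_paths: dict[str, str | Path] | None = None,
    matrix_paths: dict[str, str | Path] | None = None,
    pvalue_tables: dict[str, str | Path] | None = None,
) -> list[dict]:
    """Validate standard-format inputs, collecting (not raising) errors.

    Checks: BED start < end and non-negative, dosages in [0, 2],
    p-values in (0, 1].  Returns a list of error records with file,
    line/location and reason; empty list means all checks passed.
    """
    errors: list[dict] = []
    for name, path in (bed_paths or {}).items():
        try:
            df = hio.read_bed(path)
        except Exception as e:  # unreadable file is itself an error
            errors.append({"file": str(path), "line": None, "reason": str(e)})
            continue
        bad = df.index[(df["start"] >= df["end"]) | (df["start"] < 0)]
        for i in bad:
            errors.append(
                {"file": str(path), "line": int(i) + 1,
                 "reason": f"invalid interval {df.loc[i, 'start']}..{df.loc[i, 'end']}"}
            )
    for name, path in (dosage_paths or {}).items():
        df = hio.read_dosage_tsv(path)
        arr = df.to_numpy(float)
        bad = np.argwhere((arr < 0) | (arr > 2) | ~np.isfinite(arr))
        for vi, ii in bad:
            errors.append(
                {"file": str(path), "line": None,
                 "reason": f"dosage {arr[vi, ii]} out of [0, 2] for variant "
                           f"{df.index[vi]}, individual {df.columns[ii]}"}
            )
    for name, path in (matrix_paths or {}).items():
        df = hio.read_matrix_tsv(path)
        if df.columns.duplicated().any():
            errors.append(
                {"file": str(path), "line": None, "reason": "duplicate sample ids"}
            )
    for name, path in (pvalue_tables or {}).items():
        df = pd.read_csv(path, sep="\t")
        pcols = [c for c in df.columns if c in ("p", "p_nominal", "p_empirical")]
        for c in pcols:
            bad = df.index[(df[c] <= 0) | (df[c] > 1)]
            for i in bad:
                errors.append(
                    {"file": str(path), "line": int(i) + 2,
                     "reason": f"{c}={df.loc[i, c]} outside (0, 1]"}
                )
    return errors


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self) -> None:
        self.stages: dict[str, dict] = {}

    def record(self, stage: str, params: dict, outputs: list[Path]) -> None:
        self.stages[stage] = {
            "parameters": params,
            "outputs": {str(p): _sha256(p) for p in outputs},
            "status": "ok",
        }

    def to_dict(self) -> dict:
        from importlib.metadata import version

        try:
            v = version("haqtl")
        except Exception:
            v = "unknown"
        return {"software_version": v, "stages": self.stages}


def glink_score_table(
    cohort: synth_mod.Cohort,
    tissue: str,
    haqtl_set: qtl_mod.QTLSet,
    eqtl_loci: list[qtl_mod.LocusResult],
) -> pd.DataFrame:
    """Compute the six gLink scores plus unified score for one tissue.

    Candidates are gARE-gene pairs with TSS distance in [2 kb, 1 Mb].
    Fine-mapped eQTLs and polygenic-score weights are taken from the
    cohort's planted eQTL table (the synthetic stand-in for a
    user-provided fine-mapping table); everything else is estimated from
    the cohort data.
    """
    gare_intervals = cohort.ares[cohort.ares["are_id"].isin(haqtl_set.features)]
    candidates = glink_mod.enumerate_candidates(gare_intervals, cohort.genes)
    enominals = {lr.feature_id: lr.nominals for lr in eqtl_loci}
    g = cohort.genotypes[tissue]
    vpos = pd.Series(g.positions, index=g.variant_ids)
    dosage_frame = g.to_frame()
    fmeqtl = {
        gene: vpos.reindex(
            cohort.truth.true_eqtl.loc[
                cohort.truth.true_eqtl["gene_id"] == gene, "variant_id"
            ].unique()
        ).dropna().to_numpy()
        for gene in cohort.genes["gene_id"]
    }
    ares_by_id = cohort.ares.set_index("are_id")
    abf_h_cache: dict[str, pd.DataFrame] = {}
    abf_e_cache: dict[str, pd.DataFrame] = {}
    score_rows = []
    for c in candidates.itertuples():
        are_row = ares_by_id.loc[c.gare_id]
        enom = enominals.get(c.gene_id, pd.DataFrame())
        if len(enom) and "pos" not in enom.columns:
            enom = enom.assign(pos=vpos.reindex(enom["variant_id"]).to_numpy())
            enominals[c.gene_id] = enom
        dist, _prox = glink_mod.dist_to_fmeqtl(
            are_row["start"], are_row["end"], fmeqtl.get(c.gene_id, [])
        )
        prox_p = (
            glink_mod.proximal_eqtl_p(are_row["start"], are_row["end"], enom)
            if len(enom)
            else float("nan")
        )
        lead = haqtl_set.loci[c.gare_id].lead
        pp4 = pp_ratio_v = mr_bx = mr_by = mr_sy = np.nan
        if len(enom):
            if c.gare_id not in abf_h_cache:
                abf_h_cache[c.gare_id] = coloc_mod.wakefield_abf(
                    haqtl_set.loci[c.gare_id].nominals[["variant_id", "beta", "se"]]
                )
            if c.gene_id not in abf_e_cache:
                abf_e_cache[c.gene_id] = coloc_mod.wakefield_abf(
                    enom[["variant_id", "beta", "se"]]
                )
            try:
                post = coloc_mod.coloc_posteriors(
                    abf_h_cache[c.gare_id], abf_e_cache[c.gene_id]
                )
                pp4 = post.pp4
                pp_ratio_v = glink_mod.pp_ratio(post.pp4, post.pp3)
            except ValueError:
                pass
            hit = enom[enom["variant_id"] == lead["variant_id"]]
            if len(hit):
                mr_bx = lead["beta"]
                mr_by = float(hit["beta"].iloc[0])
                mr_sy = float(hit["se"].iloc[0])
        weights = cohort.truth.true_eqtl[
            cohort.truth.true_eqtl["gene_id"] == c.gene_id
        ].drop_duplicates("variant_id").set_index("variant_id")["beta"]
        expgs_r = np.nan
        if len(weights):
            try:
                expgs_r, _ = glink_mod.expgs_correlation(
                    dosage_frame, weights, cohort.activity[tissue].loc[c.gare_id]
                )
            except (ValueError, KeyError):
                pass
        score_rows.append(
            {
                "gare_id": c.gare_id, "gene_id": c.gene_id,
                "tss_distance": c.tss_distance,
                "gare_dist_to_fmeqtl": dist,
                "gare_proximal_eqtl_p": prox_p,
                "coloc_pp4": pp4, "coloc_pp4_pp3": pp_ratio_v,
                "beta_exposure": mr_bx,
                "beta_outcome": mr_by, "se_outcome": mr_sy,
                "expgs_corr": expgs_r,
            }
        )
    scores = pd.DataFrame(score_rows)
    if len(scores):
        mr = glink_mod.mr_test(
            scores.fillna(
                {"beta_exposure": 0.0, "beta_outcome": 0.0, "se_outcome": 1.0}
            )
        )
        scores["mr_effect"] = mr["wald_ratio"]
        scores["mr_p_adjusted"] = mr["mr_p_adjusted"]
        scores["mr_score"] = -np.log10(mr["mr_p"].clip(lower=1e-300))
        scores.loc[mr["invalid_instrument"], ["mr_effect", "mr_score"]] = np.nan
        scores["unified"] = glink_mod.unified_score(scores)
    return scores


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on a synthetic cohort; returns the manifest dict.

    All applied thresholds are logged for auditability.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest()
    logger.info(
        "thresholds: peak q<=0.01, state overlap>=50bp, binarize cutoff=%s, "
        "ubiquitous>=%s, window=%sbp, MAF>=%s, empirical p<=%s, replication "
        "p<=%s, PP4>=%s colocalized, PP4<%s eQTL-missing, candidate 2kb-1Mb, "
        "MR adjusted p<%s",
        config.binarize_cutoff, config.activity_threshold, config.window_bp,
        config.maf_min, config.empirical_threshold, config.p_share_threshold,
        config.pp4_colocalized, config.pp4_eqtl_missing, glink_mod.MR_ADJUSTED_P,
    )

    # ---- stage: simulate -------------------------------------------------
    sim = config.sim_config()
    cohort = synth_mod.simulate_cohort(
        sim, with_gwas=True, gwas_shared_fraction=config.gwas_shared_fraction
    )
    files = []
    for t in sim.tissues:
        p = out / f"dosages_{t}.tsv"
        hio.write_dosage_tsv(cohort.genotypes[t].to_frame(), p)
        files.append(p)
        p = out / f"activity_{t}.tsv"
        hio.write_matrix_tsv(cohort.activity[t], p)
        files.append(p)
        p = out / f"expression_{t}.tsv"
        hio.write_matrix_tsv(cohort.expression[t], p)
        files.append(p)
    p = out / "ares.bed"
    hio.write_bed(cohort.ares, p, ["chrom", "start", "end", "are_id"])
    files.append(p)
    p = out / "genes.tsv"
    cohort.genes.to_csv(p, sep="\t", index=False)
    files.append(p)
    p = out / "gwas.tsv"
    cohort.gwas.to_csv(p, sep="\t", index=False)
    files.append(p)
    p = out / "truth.json"
    hio.write_json(cohort.truth.to_json_dict(), p)
    files.append(p)
    manifest.record("simulate", {"seed": config.seed}, files)

    # ---- stage: quantify (fragment round-trip demo) ----------------------
    t0 = sim.tissues[0]
    act0 = cohort.activity[t0].clip(lower=0.0)
    frag_frames = []
    qs = list(act0.columns[: config.quant_samples])
    for i, s in enumerate(qs):
        frag_frames.append(
            synth_mod.simulate_fragments(
                act0[s] + 0.5,  # positive floor so every ARE row stays positive
                cohort.ares,
                mean_depth=config.mean_depth,
                fragment_length=config.fragment_length,
                seed=config.seed + 9000 + i,
                sample_id=s,
            )
        )
    fragments = pd.concat(frag_frames, ignore_index=True)
    raw = quant_mod.quantify_activity(fragments, cohort.ares)
    normalized, factors = quant_mod.size_factor_normalize(raw.clip(lower=1e-6))
    files = []
    p = out / "fragments.bed"
    hio.write_bed(fragments, p)
    files.append(p)
    p = out / "activity_raw_quantified.tsv"
    hio.write_matrix_tsv(raw, p)
    files.append(p)
    p = out / "activity_normalized.tsv"
    hio.write_matrix_tsv(normalized, p)
    files.append(p)
    p = out / "size_factors.tsv"
    factors.to_frame().to_csv(p, sep="\t")
    files.append(p)
    manifest.record(
        "quantify",
        {"mean_depth": config.mean_depth, "fragment_length": config.fragment_length},
        files,
    )

    # ---- stage: cluster --------------------------------------------------
    signal = pd.concat(
        [cohort.activity[t] for t in sim.tissues], axis=1
    )
    binary = modules_mod.binarize_signal(signal, cutoff=config.binarize_cutoff)
    assignment = modules_mod.kcentroid_cluster(
        binary, k=config.n_modules, n_restarts=config.n_restarts, seed=config.seed
    )
    module_means = signal.groupby(assignment.labels).mean()
    sample_clusters = modules_mod.cluster_samples(
        module_means, n_clusters=min(config.n_sample_clusters, signal.shape[1])
    )
    groups = modules_mod.assign_groups(
        assignment, signal, sample_clusters, config.activity_threshold
    )
    files = []
    p = out / "are_modules.tsv"
    assignment.labels.to_frame().to_csv(p, sep="\t")
    files.append(p)
    p = out / "module_groups.tsv"
    groups.table.to_csv(p, sep="\t")
    files.append(p)
    p = out / "module_centroids.json"
    hio.write_json({"centroids": assignment.centroids}, p)
    files.append(p)
    manifest.record(
        "cluster",
        {"cutoff": config.binarize_cutoff, "k": config.n_modules},
        files,
    )

    # ---- stage: qtl per tissue -------------------------------------------
    centers = pd.Series(
        cohort.ares["center"].to_numpy(), index=cohort.ares["are_id"]
    )
    qtl_results: dict[str, tuple[list, qtl_mod.QTLSet]] = {}
    files = []
    for k_t, t in enumerate(sim.tissues):
        loci, qset = qtl_mod.map_qtls(
            cohort.activity[t],
            centers,
            cohort.genotypes[t],
            covariates=cohort.covariates[t],
            n_latent_factors=config.n_latent_factors,
            window_bp=config.window_bp,
            maf_min=config.maf_min,
            n_permutations=config.n_permutations,
            seed=config.seed + 100 + k_t,
        )
        qtl_results[t] = (loci, qset)
        rows = [
            {
                "feature_id": lr.feature_id,
                "lead_variant": lr.lead["variant_id"],
                "beta": lr.lead["beta"],
                "se": lr.lead["se"],
                "p_nominal": lr.lead["p_nominal"],
                "beta_shape1": lr.beta_shape1,
                "beta_shape2": lr.beta_shape2,
                "p_empirical": lr.p_empirical,
                "p_empirical_direct": lr.p_empirical_direct,
                "nominal_threshold": lr.nominal_threshold,
                "is_gare": lr.feature_id in qset.features,
            }
            for lr in loci
        ]
        p = out / f"qtl_loci_{t}.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        files.append(p)
    manifest.record(
        "qtl",
        {"window_bp": config.window_bp, "maf_min": config.maf_min,
         "n_permutations": config.n_permutations,
         "empirical_threshold": config.empirical_threshold},
        files,
    )

    # ---- stage: sharing --------------------------------------------------
    files = []
    sharing_rows = []
    label_frames = []
    presence = pd.DataFrame(
        True, index=cohort.ares["are_id"], columns=sim.tissues
    )  # synthetic AREs are defined genome-wide in every tissue
    gares_per_tissue = {t: qtl_results[t][1].features for t in sim.tissues}
    replication_p: dict[tuple[str, str, str], float] = {}
    for t1 in sim.tissues:
        loci1, qset1 = qtl_results[t1]
        leads = pd.DataFrame(
            [
                {
                    "feature_id": f,
                    "variant_id": qset1.loci[f].lead["variant_id"],
                    "beta": qset1.loci[f].lead["beta"],
                    "p_nominal": qset1.loci[f].lead["p_nominal"],
                }
                for f in qset1.features
            ]
        )
        for t2 in sim.tissues:
            if t2 == t1 or not len(leads):
                continue
            loci2, _ = qtl_results[t2]
            rep_nominals = pd.concat(
                [lr.nominals for lr in loci2], ignore_index=True
            )
            pairs = sharing_mod.pair_leads(
                leads, rep_nominals, presence, t1, t2
            )
            for r in pairs.itertuples():
                replication_p[(r.gare_id, t1, t2)] = r.p_replication
            if len(pairs):
                bins = sharing_mod.consistency_by_bin(pairs)
                est = sharing_mod.sharing_proportion(bins, t1, t2)
                sharing_rows.append(
                    {"discovery": t1, "replication": t2,
                     "sharing": est.sharing, "sharing_raw": est.sharing_raw,
                     "n_pairs": int(bins.table["count"].sum())}
                )
    labels = sharing_mod.classify_gare_types(
        gares_per_tissue, presence, replication_p, config.p_share_threshold
    )
    p = out / "tissue_sharing.tsv"
    pd.DataFrame(sharing_rows).to_csv(p, sep="\t", index=False)
    files.append(p)
    p = out / "gare_types.tsv"
    labels.to_csv(p, sep="\t", index=False)
    files.append(p)
    manifest.record("sharing", {"p_share_threshold": config.p_share_threshold}, files)

    # ---- stage: coloc ----------------------------------------------------
    t0 = sim.tissues[0]
    loci0, qset0 = qtl_results[t0]
    n0 = cohort.genotypes[t0].n_individuals
    gwas = cohort.gwas.rename(columns={"p": "p_gwas"})
    gwas_abf = coloc_mod.wakefield_abf(
        gwas[["variant_id", "beta", "se"]].assign(trait_type="quantitative")
    )
    coloc_rows = []
    gare_coloc_flags: dict[str, bool] = {}
    for f in qset0.features:
        nom = qset0.loci[f].nominals
        abf_h = coloc_mod.wakefield_abf(
            nom.rename(columns={"variant_id": "variant_id"})[
                ["variant_id", "beta", "se"]
            ]
        )
        post = coloc_mod.coloc_posteriors(gwas_abf, abf_h)
        cls = coloc_mod.classify_loci(
            post, None, config.pp4_colocalized, config.pp4_eqtl_missing
        )
        gare_coloc_flags[f] = cls["colocalized"]
        coloc_rows.append(
            {"gare_id": f, **{f"pp{i}": post[i] for i in range(5)},
             "colocalized": cls["colocalized"]}
        )
    files = []
    p = out / "coloc_gwas_haqtl.tsv"
    pd.DataFrame(coloc_rows).to_csv(p, sep="\t", index=False)
    files.append(p)
    manifest.record(
        "coloc",
        {"pp4_colocalized": config.pp4_colocalized,
         "pp4_eqtl_missing": config.pp4_eqtl_missing},
        files,
    )

    # ---- stage: glink ----------------------------------------------------
    eloci, _eqset = qtl_mod.map_qtls(
        cohort.expression[t0],
        pd.Series(cohort.genes["tss"].to_numpy(), index=cohort.genes["gene_id"]),
        cohort.genotypes[t0],
        covariates=cohort.covariates[t0],
        n_latent_factors=config.n_latent_factors,
        window_bp=config.window_bp,
        maf_min=config.maf_min,
        n_permutations=config.n_permutations,
        seed=config.seed + 555,
    )
    scores = glink_score_table(cohort, t0, qset0, eloci)
    files = []
    p = out / "glink_scores.tsv"
    scores.to_csv(p, sep="\t", index=False)
    files.append(p)
    manifest.record("glink", {"link_quantile": config.link_quantile}, files)

    # ---- stage: enrichment ------------------------------------------------
    report: dict = {"n_gares": len(qset0.features)}
    if len(scores) and scores["unified"].notna().any():
        cut = scores["unified"].quantile(config.link_quantile)
        linked = set(scores.loc[scores["unified"] >= cut, "gare_id"])
        if linked and qset0.features:
            try:
                pl, pb, pval = glink_mod.colocalized_gare_enrichment(
                    linked, set(qset0.features), gare_coloc_flags
                )
                report.update(
                    {"prop_linked": pl, "prop_background": pb, "enrichment_p": pval}
                )
            except ValueError:
                pass
    files = []
    p = out / "enrichment.json"
    hio.write_json(report, p)
    files.append(p)
    manifest.record("enrichment", {"link_quantile": config.link_quantile}, files)

    mdict = manifest.to_dict()
    hio.write_json(mdict, out / "manifest.json")
    return mdict
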