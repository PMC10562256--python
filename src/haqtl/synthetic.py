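"""Synthetic multitissue cohort generator with known ground truth.

Emulates the study design the rest of the package analyses: multi-individual
genotypes with blockwise LD, H3K27ac-like ARE activities with planted cis
effects and configurable cross-tissue sharing, gene expression with planted
eQTLs optionally sharing causal variants with haQTLs, fragment sets that
invert the activity formula, and GWAS summary statistics with planted
colocalization.  Every operation is a pure function of (inputs, seed).

The generative model for activity is linear-Gaussian:

    activity = beta * dosage + covariates @ loadings + noise,

matching the additive model the cis-QTL regression assumes.  LD is a
blockwise AR(1) Gaussian copula thresholded to Hardy-Weinberg dosages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfigurationError",
    "SimConfig",
    "SimTruth",
    "GenotypeMatrix",
    "Cohort",
    "simulate_genotypes",
    "simulate_activity",
    "simulate_expression",
    "simulate_fragments",
    "simulate_gwas",
    "simulate_cohort",
    "simulate_lead_pairs",
]


class ConfigurationError(ValueError):
    """Raised for out-of-bounds simulation parameters."""


@dataclass
class GenotypeMatrix:
    """Variant x individual dosage matrix with positions and frequencies."""

    dosages: np.ndarray  # (n_variants, n_individuals), values in {0,1,2}
    variant_ids: list[str]
    chrom: str
    positions: np.ndarray  # bp, ascending
    individual_ids: list[str]
    allele_freqs: np.ndarray  # configured alt-allele frequencies

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[1]

    def maf(self) -> np.ndarray:
        """Empirical minor-allele frequency per variant."""
        f = self.dosages.mean(axis=1) / 2.0
        return np.minimum(f, 1.0 - f)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosages, index=self.variant_ids, columns=self.individual_ids
        )


@dataclass
class SimConfig:
    """Cohort design: sizes, allele frequencies, LD, effects and sharing."""

    n_individuals_per_tissue: dict[str, int]
    n_variants: int = 400
    n_ares: int = 100
    n_genes: int = 40
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 20
    ld_rho: float = 0.6
    haqtl_effect_sd: float = 0.8
    eqtl_effect_sd: float = 0.8
    noise_sd: float = 1.0
    sharing_matrix: pd.DataFrame | None = None
    frac_shared_causal: float = 0.5
    covariate_count: int = 2
    seed: int = 0
    variant_spacing: int = 2_000
    are_length: int = 500

    @property
    def tissues(self) -> list[str]:
        return list(self.n_individuals_per_tissue)

    def __post_init__(self) -> None:
        if self.sharing_matrix is None:
            t = self.tissues
            m = np.full((len(t), len(t)), 0.5)
            np.fill_diagonal(m, 1.0)
            self.sharing_matrix = pd.DataFrame(m, index=t, columns=t)
        self.validate()

    def validate(self) -> None:
        if not self.n_individuals_per_tissue:
            raise ConfigurationError("at least one tissue required")
        for t, n in self.n_individuals_per_tissue.items():
            if n < 2:
                raise ConfigurationError(f"tissue {t}: need >= 2 individuals")
        for name in ("n_variants", "n_ares", "n_genes", "ld_block_size"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie in (0, 0.5]")
        if not 0 <= self.ld_rho < 1:
            raise ConfigurationError("ld_rho must lie in [0, 1)")
        if self.haqtl_effect_sd < 0 or self.eqtl_effect_sd < 0:
            raise ConfigurationError("effect sds must be non-negative")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if not 0 <= self.frac_shared_causal <= 1:
            raise ConfigurationError("frac_shared_causal must lie in [0, 1]")
        if self.covariate_count < 0:
            raise ConfigurationError("covariate_count must be non-negative")
        sm = self.sharing_matrix
        t = self.tissues
        if list(sm.index) != t or list(sm.columns) != t:
            raise ConfigurationError("sharing_matrix must be indexed by the tissues")
        a = sm.to_numpy(float)
        if not np.allclose(a, a.T) or not np.allclose(np.diag(a), 1.0):
            raise ConfigurationError("sharing_matrix must be symmetric with unit diagonal")
        if ((a < 0) | (a > 1)).any():
            raise ConfigurationError("sharing probabilities must lie in [0, 1]")


@dataclass
class SimTruth:
    """Planted effects and links; the ground truth downstream stages chase."""

    true_haqtl: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["are_id", "tissue", "variant_id", "beta"]
        )
    )
    true_eqtl: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["gene_id", "tissue", "variant_id", "beta"]
        )
    )
    true_links: list[tuple[str, str]] = field(default_factory=list)
    true_sharing: dict[tuple[str, str], float] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "true_haqtl": self.true_haqtl.to_dict(orient="records"),
            "true_eqtl": self.true_eqtl.to_dict(orient="records"),
            "true_links": [list(p) for p in self.true_links],
            "true_sharing": {f"{a}|{b}": v for (a, b), v in self.true_sharing.items()},
        }


@dataclass
class Cohort:
    """A fully simulated cohort plus its ground truth."""

    config: SimConfig
    genotypes: dict[str, GenotypeMatrix]
    activity: dict[str, pd.DataFrame]  # tissue -> ARE x individual
    covariates: dict[str, pd.DataFrame]  # tissue -> individual x covariate
    expression: dict[str, pd.DataFrame]  # tissue -> gene x individual
    ares: pd.DataFrame  # chrom, start, end, are_id, center
    genes: pd.DataFrame  # gene_id, chrom, tss
    truth: SimTruth
    gwas: pd.DataFrame | None = None


def _spawn(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))


def simulate_genotypes(
    n_individuals: int,
    n_variants: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_block_size: int = 20,
    ld_rho: float = 0.6,
    seed: int = 0,
    chrom: str = "chr1",
    variant_spacing: int = 2_000,
    individual_prefix: str = "ind",
) -> GenotypeMatrix:
    """Draw Hardy-Weinberg dosages with blockwise AR(1) LD.

    Two latent haplotypes per individual are drawn from an AR(1) Gaussian
    within each LD block and thresholded at the normal quantile of each
    variant's allele frequency, so adjacent variants in a block share
    latent correlation ``ld_rho`` while blocks are independent.
    """
    if n_individuals < 2 or n_variants < 1:
        raise ConfigurationError("need >= 2 individuals and >= 1 variant")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ConfigurationError("maf_range must lie in (0, 0.5]")
    if not 0 <= ld_rho < 1:
        raise ConfigurationError("ld_rho must lie in [0, 1)")
    if ld_block_size < 1:
        raise ConfigurationError("ld_block_size must be positive")

    rng = _spawn(seed, 1)
    freqs = rng.uniform(lo, hi, size=n_variants)
    thresh = stats.norm.ppf(freqs)

    dosage = np.zeros((n_variants, n_individuals), dtype=np.int8)
    for _hap in range(2):
        z = np.empty((n_variants, n_individuals))
        eps = rng.standard_normal((n_variants, n_individuals))
        scale = np.sqrt(1.0 - ld_rho**2)
        for v in range(n_variants):
            if v % ld_block_size == 0:
                z[v] = eps[v]
            else:
                z[v] = ld_rho * z[v - 1] + scale * eps[v]
        dosage += (z < thresh[:, None]).astype(np.int8)

    positions = (np.arange(n_variants, dtype=np.int64) + 1) * variant_spacing
    return GenotypeMatrix(
        dosages=dosage.astype(float),
        variant_ids=[f"var{v}" for v in range(n_variants)],
        chrom=chrom,
        positions=positions,
        individual_ids=[f"{individual_prefix}{i}" for i in range(n_individuals)],
        allele_freqs=freqs,
    )


def _are_layout(config: SimConfig) -> pd.DataFrame:
    span = config.n_variants * config.variant_spacing
    centers = np.linspace(
        span * 0.05, span * 0.95, config.n_ares, dtype=np.int64
    )
    half = config.are_length // 2
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "start": centers - half,
            "end": centers - half + config.are_length,
            "are_id": [f"are{i}" for i in range(config.n_ares)],
            "center": centers,
        }
    )


def simulate_activity(
    genotypes: dict[str, GenotypeMatrix],
    config: SimConfig,
    seed: int | None = None,
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame], pd.DataFrame, SimTruth]:
    """Simulate per-tissue ARE activity with planted cis effects.

    Each ARE is assigned a causal variant within 25 kb of its center and a
    base tissue (round-robin).  When ``haqtl_effect_sd > 0`` an effect
    ``beta ~ N(0, haqtl_effect_sd)`` is planted in the base tissue and
    copied (same variant, same beta, hence same sign) into every other
    tissue with the probability in ``sharing_matrix``.

    Returns ``(activity, covariates, ares, truth)``.
    """
    missing = [t for t in config.tissues if t not in genotypes]
    if missing:
        raise ConfigurationError(f"genotypes missing for tissues {missing}")
    seed = config.seed if seed is None else seed
    rng = _spawn(seed, 2)
    ares = _are_layout(config)
    tissues = config.tissues

    any_g = genotypes[tissues[0]]
    positions = any_g.positions

    causal_idx = np.empty(config.n_ares, dtype=int)
    for i, c in enumerate(ares["center"]):
        near = np.flatnonzero(np.abs(positions - c) <= 25_000)
        if near.size == 0:
            near = np.array([np.argmin(np.abs(positions - c))])
        causal_idx[i] = rng.choice(near)

    base_tissue = [tissues[i % len(tissues)] for i in range(config.n_ares)]
    betas = (
        rng.normal(0.0, config.haqtl_effect_sd, size=config.n_ares)
        if config.haqtl_effect_sd > 0
        else np.zeros(config.n_ares)
    )

    planted: dict[str, dict[int, float]] = {t: {} for t in tissues}
    records = []
    if config.haqtl_effect_sd > 0:
        for i in range(config.n_ares):
            bt = base_tissue[i]
            planted[bt][i] = betas[i]
            for t2 in tissues:
                if t2 == bt:
                    continue
                if rng.random() < config.sharing_matrix.loc[bt, t2]:
                    planted[t2][i] = betas[i]
        for t in tissues:
            for i, b in planted[t].items():
                records.append(
                    {
                        "are_id": ares["are_id"][i],
                        "tissue": t,
                        "variant_id": any_g.variant_ids[causal_idx[i]],
                        "beta": b,
                    }
                )

    loadings = rng.normal(0.0, 0.5, size=(config.n_ares, config.covariate_count))
    if config.covariate_count >= 1:
        # first covariate mimics a cell-fraction confounder loading broadly
        loadings[:, 0] = rng.normal(0.5, 0.25, size=config.n_ares)

    activity: dict[str, pd.DataFrame] = {}
    covariates: dict[str, pd.DataFrame] = {}
    for t in tissues:
        g = genotypes[t]
        n = g.n_individuals
        cov = rng.standard_normal((n, config.covariate_count))
        noise = rng.normal(0.0, config.noise_sd, size=(config.n_ares, n))
        act = loadings @ cov.T + noise
        for i, b in planted[t].items():
            act[i] += b * g.dosages[causal_idx[i]]
        activity[t] = pd.DataFrame(
            act, index=ares["are_id"], columns=g.individual_ids
        )
        covariates[t] = pd.DataFrame(
            cov,
            index=g.individual_ids,
            columns=[f"cov{j}" for j in range(config.covariate_count)],
        )

    truth = SimTruth(
        true_haqtl=pd.DataFrame(
            records, columns=["are_id", "tissue", "variant_id", "beta"]
        )
    )
    for a_i, t1 in enumerate(tissues):
        for t2 in tissues[a_i + 1 :]:
            shared = sum(
                1 for i in range(config.n_ares) if i in planted[t1] and i in planted[t2]
            )
            denom = sum(
                1 for i in range(config.n_ares) if i in planted[t1] or i in planted[t2]
            )
            truth.true_sharing[(t1, t2)] = shared / denom if denom else 0.0
    return activity, covariates, ares, truth


def simulate_expression(
    genotypes: dict[str, GenotypeMatrix],
    config: SimConfig,
    truth: SimTruth,
    seed: int | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, SimTruth]:
    """Simulate gene expression with planted eQTLs.

    Each gene is paired with a designated ARE (genes spread across AREs);
    for a ``frac_shared_causal`` fraction of pairs whose ARE carries a
    planted haQTL, the gene's causal variant *is* the ARE's causal variant
    and the pair is recorded in ``true_links``; other genes get a distinct
    causal variant near their TSS.

    Returns ``(expression, genes, truth)`` with truth updated in place.
    """
    seed = config.seed if seed is None else seed
    rng = _spawn(seed, 3)
    tissues = config.tissues
    any_g = genotypes[tissues[0]]
    ares = _are_layout(config)

    pair_are = [int(g * config.n_ares / config.n_genes) for g in range(config.n_genes)]
    # one causal variant per ARE (identical across tissues); last record wins
    haqtl_by_are = {r.are_id: r for r in truth.true_haqtl.itertuples()}

    tss = []
    gene_rows = []
    for g_i in range(config.n_genes):
        a = ares.iloc[pair_are[g_i]]
        offset = int(rng.uniform(2_000, 50_000)) * (1 if rng.random() < 0.5 else -1)
        gene_tss = max(0, int(a["center"]) + offset)
        tss.append(gene_tss)
        gene_rows.append(
            {"gene_id": f"gene{g_i}", "chrom": "chr1", "tss": gene_tss,
             "paired_are": a["are_id"]}
        )
    genes = pd.DataFrame(gene_rows)

    positions = any_g.positions
    records = []
    links = []
    shared_flags = rng.random(config.n_genes) < config.frac_shared_causal
    for g_i in range(config.n_genes):
        are_id = genes["paired_are"][g_i]
        beta = (
            rng.normal(0.0, config.eqtl_effect_sd)
            if config.eqtl_effect_sd > 0
            else 0.0
        )
        if beta == 0.0:
            continue
        if shared_flags[g_i] and are_id in haqtl_by_are:
            variant_id = haqtl_by_are[are_id].variant_id
            links.append((are_id, f"gene{g_i}"))
        else:
            near = np.flatnonzero(np.abs(positions - tss[g_i]) <= 100_000)
            if near.size == 0:
                near = np.array([int(np.argmin(np.abs(positions - tss[g_i])))])
            variant_id = any_g.variant_ids[int(rng.choice(near))]
        for t in tissues:
            records.append(
                {"gene_id": f"gene{g_i}", "tissue": t, "variant_id": variant_id,
                 "beta": beta}
            )

    expr: dict[str, pd.DataFrame] = {}
    rec_df = pd.DataFrame(records, columns=["gene_id", "tissue", "variant_id", "beta"])
    vidx = {v: i for i, v in enumerate(any_g.variant_ids)}
    for t in tissues:
        g = genotypes[t]
        n = g.n_individuals
        e = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n))
        sub = rec_df[rec_df["tissue"] == t]
        for r in sub.itertuples():
            gi = int(r.gene_id.removeprefix("gene"))
            e[gi] += r.beta * g.dosages[vidx[r.variant_id]]
        expr[t] = pd.DataFrame(
            e, index=[f"gene{i}" for i in range(config.n_genes)],
            columns=g.individual_ids,
        )

    truth.true_eqtl = rec_df
    truth.true_links = links
    return expr, genes.drop(columns="paired_are"), truth


def simulate_fragments(
    activity_row: pd.Series,
    are_intervals: pd.DataFrame,
    mean_depth: float = 10.0,
    fragment_length: int = 200,
    seed: int = 0,
    sample_id: str = "s0",
) -> pd.DataFrame:
    """Draw a fragment set whose expected quantified activity is depth-scaled.

    Per ARE the fragment count is Poisson with mean
    ``mean_depth * activity * length / eff_len`` where ``eff_len`` is the
    fragment length clipped to the ARE length; fragments are placed
    uniformly, fully inside the ARE, so the expected value of
    ``quant.quantify_activity`` equals ``mean_depth * activity``.
    """
    if mean_depth < 0:
        raise ConfigurationError("mean_depth must be non-negative")
    if (activity_row < 0).any():
        raise ConfigurationError("activities must be non-negative")
    rng = _spawn(seed, 4)
    rows = []
    for r in are_intervals.itertuples():
        a = float(activity_row.get(r.are_id, 0.0))
        if a == 0.0:
            continue
        length = r.end - r.start
        eff = min(fragment_length, length)
        lam = mean_depth * a * length / eff
        count = rng.poisson(lam)
        if count == 0:
            continue
        starts = rng.integers(r.start, r.end - eff + 1, size=count)
        for s in starts:
            rows.append((r.chrom, int(s), int(s) + eff, sample_id))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "sample"])


def simulate_gwas(
    genotypes: GenotypeMatrix,
    truth: SimTruth,
    shared_fraction: float = 0.5,
    n_gwas: int = 50_000,
    seed: int = 0,
    causal_z: float = 10.0,
    trait_type: str = "quantitative",
) -> pd.DataFrame:
    """Simulate GWAS summary statistics with planted colocalization.

    A ``shared_fraction`` of the planted haQTL causal variants is made
    GWAS-causal with non-centrality ``causal_z``; marginal z-scores are
    drawn from N(R @ lambda, R) with R the empirical dosage correlation,
    so LD neighbours of a causal variant carry proportional signal.
    Standard errors follow 1 / sqrt(2 * maf * (1 - maf) * n_gwas).
    """
    if n_gwas < 2:
        raise ConfigurationError("n_gwas must be >= 2")
    if not 0 <= shared_fraction <= 1:
        raise ConfigurationError("shared_fraction must lie in [0, 1]")
    rng = _spawn(seed, 5)

    causal_variants = sorted(set(truth.true_haqtl["variant_id"]))
    n_causal = int(round(shared_fraction * len(causal_variants)))
    chosen = (
        list(rng.choice(causal_variants, size=n_causal, replace=False))
        if n_causal
        else []
    )

    D = genotypes.dosages
    Ds = D - D.mean(axis=1, keepdims=True)
    sd = Ds.std(axis=1)
    sd[sd == 0] = 1.0
    Ds /= sd[:, None]
    R = (Ds @ Ds.T) / genotypes.n_individuals
    R += 1e-4 * np.eye(genotypes.n_variants)

    lam = np.zeros(genotypes.n_variants)
    vidx = {v: i for i, v in enumerate(genotypes.variant_ids)}
    # one effect sign per 200 kb neighbourhood so nearby causal variants in
    # LD reinforce rather than cancel each other's marginal signal
    region_sign: dict[int, float] = {}
    for v in chosen:
        region = int(genotypes.positions[vidx[v]]) // 200_000
        if region not in region_sign:
            region_sign[region] = 1.0 if rng.random() < 0.5 else -1.0
        lam[vidx[v]] = region_sign[region] * causal_z
    mean = R @ lam
    L = np.linalg.cholesky(R)
    z = mean + L @ rng.standard_normal(genotypes.n_variants)

    f = genotypes.allele_freqs
    maf = np.minimum(f, 1 - f)
    se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n_gwas)
    return pd.DataFrame(
        {
            "variant_id": genotypes.variant_ids,
            "chrom": genotypes.chrom,
            "pos": genotypes.positions,
            "beta": z * se,
            "se": se,
            "p": 2.0 * stats.norm.sf(np.abs(z)),
            "n": n_gwas,
            "trait_type": trait_type,
            "gwas_causal": [genotypes.variant_ids[i] in set(chosen)
                            for i in range(genotypes.n_variants)],
        }
    )


def simulate_cohort(
    config: SimConfig, with_gwas: bool = True, gwas_shared_fraction: float = 0.5
) -> Cohort:
    """Simulate genotypes, activity, expression and GWAS for every tissue."""
    genotypes = {
        t: simulate_genotypes(
            n,
            config.n_variants,
            config.maf_range,
            config.ld_block_size,
            config.ld_rho,
            seed=config.seed + 1000 * k,
            variant_spacing=config.variant_spacing,
            individual_prefix=f"{t}_ind",
        )
        for k, (t, n) in enumerate(config.n_individuals_per_tissue.items())
    }
    activity, covariates, ares, truth = simulate_activity(genotypes, config)
    expression, genes, truth = simulate_expression(genotypes, config, truth)
    gwas = None
    if with_gwas:
        gwas = simulate_gwas(
            genotypes[config.tissues[0]],
            truth,
            shared_fraction=gwas_shared_fraction,
            seed=config.seed + 77,
        )
    return Cohort(
        config=config,
        genotypes=genotypes,
        activity=activity,
        covariates=covariates,
        expression=expression,
        ares=ares,
        genes=genes,
        truth=truth,
        gwas=gwas,
    )


def simulate_lead_pairs(
    n_pairs: int,
    sharing: float,
    seed: int = 0,
    beta_low: float = 0.3,
    beta_high: float = 1.0,
    rep_se: float = 0.1,
) -> pd.DataFrame:
    """Simulate discovery/replication lead-haQTL pairs with planted sharing.

    A ``sharing`` fraction of pairs carries the same true effect in both
    tissues (same sign; replication z = beta/rep_se + noise); the rest are
    null in the replication tissue (independent sign, uniform p).  Used to
    validate the directionality-consistency sharing estimator.
    """
    if not 0 <= sharing <= 1:
        raise ConfigurationError("sharing must lie in [0, 1]")
    rng = _spawn(seed, 6)
    shared = rng.random(n_pairs) < sharing
    mag = rng.uniform(beta_low, beta_high, size=n_pairs)
    sign = np.where(rng.random(n_pairs) < 0.5, 1.0, -1.0)
    beta_disc = sign * mag

    z_rep = np.where(
        shared,
        beta_disc / rep_se + rng.standard_normal(n_pairs),
        rng.standard_normal(n_pairs),
    )
    beta_rep = z_rep * rep_se
    p_rep = 2.0 * stats.norm.sf(np.abs(z_rep))
    return pd.DataFrame(
        {
            "gare_id": [f"gare{i}" for i in range(n_pairs)],
            "variant_id": [f"var{i}" for i in range(n_pairs)],
            "beta_discovery": beta_disc,
            "p_discovery": 2.0 * stats.norm.sf(np.abs(beta_disc / rep_se)),
            "beta_replication": beta_rep,
            "p_replication": p_rep,
            "discovery_tissue": "t1",
            "replication_tissue": "t2",
            "truly_shared": shared,
        }
    )
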