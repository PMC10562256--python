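"""gLink scores: genetic ARE-gene linking.

Six scores connect a genetically influenced ARE (gARE) to a candidate
target gene: (1) distance from the gARE to the gene's fine-mapped eQTLs,
(2) the best nominal p of gARE-proximal eQTLs, (3) colocalization PP4 of
the haQTL and eQTL signals, (4) the PP4/PP3 ratio, (5) the Mendelian-
randomization Wald ratio using the lead haQTL as instrument, and (6) the
correlation between gARE activity and polygenic-score-predicted gene
expression.  A unified score aggregates oriented percentile ranks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

__all__ = [
    "enumerate_candidates",
    "dist_to_fmeqtl",
    "proximal_eqtl_p",
    "mr_test",
    "ivw_estimate",
    "expgs_correlation",
    "unified_score",
    "colocalized_gare_enrichment",
]

MIN_TSS_DISTANCE = 2_000
MAX_TSS_DISTANCE = 1_000_000
PROXIMAL_WINDOW = 2_000
MR_ADJUSTED_P = 0.2
PP_RATIO_CAP = 1e6


def enumerate_candidates(
    gares: pd.DataFrame, gene_tss: pd.DataFrame
) -> pd.DataFrame:
    """All gARE-gene pairs with TSS distance in [2 kb, 1 Mb].

    ``gares`` needs ``are_id, chrom, start, end``; ``gene_tss`` needs
    ``gene_id, chrom, tss``.  Distance is the minimum over the gARE's
    boundary points of |boundary - TSS|, computed within chromosomes.
    """
    rows = []
    for g in gares.itertuples():
        genes = gene_tss[gene_tss["chrom"] == g.chrom]
        d = np.minimum(
            np.abs(genes["tss"].to_numpy() - g.start),
            np.abs(genes["tss"].to_numpy() - g.end),
        )
        keep = (d >= MIN_TSS_DISTANCE) & (d <= MAX_TSS_DISTANCE)
        for gene_id, dist in zip(genes["gene_id"].to_numpy()[keep], d[keep]):
            rows.append({"gare_id": g.are_id, "gene_id": gene_id, "tss_distance": int(dist)})
    return pd.DataFrame(rows, columns=["gare_id", "gene_id", "tss_distance"])


def _interval_distance(pos: np.ndarray, start: int, end: int) -> np.ndarray:
    """bp distance from positions to a half-open interval (0 if inside)."""
    pos = np.asarray(pos, dtype=float)
    return np.where(
        pos < start, start - pos, np.where(pos >= end, pos - end + 1, 0.0)
    )


def dist_to_fmeqtl(
    gare_start: int, gare_end: int, fmeqtl_positions: np.ndarray | list[int]
) -> tuple[float, bool]:
    """Minimum distance from the gene's fine-mapped eQTLs to the gARE.

    Returns ``(distance, proximal)`` with distance 0 when an FMeQTL lies
    inside the gARE, ``inf`` when the gene has none, and proximal true
    iff distance <= 2 kb.
    """
    pos = np.asarray(fmeqtl_positions, dtype=float)
    if pos.size == 0:
        return float("inf"), False
    d = float(_interval_distance(pos, gare_start, gare_end).min())
    return d, d <= PROXIMAL_WINDOW


def proximal_eqtl_p(
    gare_start: int,
    gare_end: int,
    gene_nominal_eqtls: pd.DataFrame,
    window: int = PROXIMAL_WINDOW,
) -> float:
    """Best (minimum) nominal eQTL p among variants within 2 kb of the gARE.

    ``gene_nominal_eqtls`` needs ``pos`` and ``p_nominal``; returns NaN
    when no variant falls in the window.
    """
    if not len(gene_nominal_eqtls):
        return float("nan")
    d = _interval_distance(
        gene_nominal_eqtls["pos"].to_numpy(), gare_start, gare_end
    )
    sub = gene_nominal_eqtls.loc[d <= window, "p_nominal"]
    return float(sub.min()) if len(sub) else float("nan")


def mr_test(pairs_stats: pd.DataFrame) -> pd.DataFrame:
    """Wald-ratio Mendelian randomization across candidate pairs.

    One row per pair with ``beta_exposure, se_exposure, beta_outcome,
    se_outcome`` at the instrument (the gARE's lead haQTL; exposure =
    gARE activity, outcome = expression).  The ratio is
    beta_outcome / beta_exposure with first-order delta-method standard
    error se_outcome / |beta_exposure|; p-values are two-sided normal and
    Benjamini-Hochberg adjusted across all valid pairs.  Pairs with a
    null exposure effect are flagged invalid-instrument.
    """
    out = pairs_stats.copy()
    bx = out["beta_exposure"].to_numpy(float)
    by = out["beta_outcome"].to_numpy(float)
    sy = out["se_outcome"].to_numpy(float)
    valid = np.abs(bx) >= 1e-12
    ratio = np.where(valid, by / np.where(valid, bx, 1.0), np.nan)
    se = np.where(valid, sy / np.abs(np.where(valid, bx, 1.0)), np.nan)
    z = ratio / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    out["wald_ratio"] = ratio
    out["mr_se"] = se
    out["mr_p"] = p
    out["invalid_instrument"] = ~valid
    out["mr_p_adjusted"] = np.nan
    if valid.any():
        out.loc[valid, "mr_p_adjusted"] = multipletests(p[valid], method="fdr_bh")[1]
    out["mr_significant"] = out["mr_p_adjusted"] < MR_ADJUSTED_P
    return out


def ivw_estimate(ratios: np.ndarray, ses: np.ndarray) -> tuple[float, float]:
    """Inverse-variance-weighted combination of per-instrument Wald ratios."""
    w = 1.0 / np.asarray(ses, float) ** 2
    est = float(np.sum(w * ratios) / np.sum(w))
    return est, float(np.sqrt(1.0 / np.sum(w)))


def expgs_correlation(
    dosages: pd.DataFrame | np.ndarray,
    eqtl_weights: pd.Series | dict[str, float],
    gare_activity: pd.Series | np.ndarray,
) -> tuple[float, float]:
    """Correlate gARE activity with polygenic-score-predicted expression.

    ``dosages`` is variant x individual; ``eqtl_weights`` maps variant id
    to effect size (the gene's independent eQTLs).  The predicted
    expression per individual is sum(weight * dosage); returns the
    Pearson r with the activity vector and its two-sided p.
    """
    w = pd.Series(eqtl_weights, dtype=float)
    if not len(w):
        raise ValueError("need at least one eQTL weight")
    D = dosages.loc[w.index] if isinstance(dosages, pd.DataFrame) else dosages
    score = np.asarray(D, float).T @ w.to_numpy()
    if np.var(score) == 0:
        raise ValueError("polygenic score has zero variance")
    r, p = stats.pearsonr(score, np.asarray(gare_activity, float))
    return float(r), float(p)


# orientation of each component: 'larger' = larger is stronger evidence
_COMPONENT_ORIENT = {
    "gare_dist_to_fmeqtl": "smaller",
    "gare_proximal_eqtl_p": "smaller",
    "coloc_pp4": "larger",
    "coloc_pp4_pp3": "larger",
    "mr_score": "larger",
    "expgs_corr": "larger",
}


def unified_score(
    score_table: pd.DataFrame, components: list[str] | None = None
) -> pd.Series:
    """Mean oriented percentile rank over available component scores.

    Each component column is ranked across candidate pairs with the
    orientation "larger = stronger link" (distances and p-values are
    inverted); a pair's unified score is the mean of its available
    component percentiles, NaN components ignored (all-NaN -> NaN).
    The top pair in every component scores 1.
    """
    components = components or [
        c for c in _COMPONENT_ORIENT if c in score_table.columns
    ]
    if not components:
        raise ValueError("no component score columns found")
    pct = pd.DataFrame(index=score_table.index, columns=components, dtype=float)
    for c in components:
        v = score_table[c].to_numpy(float)
        if _COMPONENT_ORIENT.get(c, "larger") == "smaller":
            v = -v
        v = np.where(np.isinf(v), -np.inf, v)
        mask = ~np.isnan(v)
        if mask.sum():
            ranks = stats.rankdata(v[mask], method="average")
            pct.loc[score_table.index[mask], c] = ranks / mask.sum()
    return pct.mean(axis=1, skipna=True).rename("unified")


def colocalized_gare_enrichment(
    linked_gares: set[str] | list[str],
    all_gares: set[str] | list[str],
    colocalized_flags: dict[str, bool] | pd.Series,
) -> tuple[float, float, float]:
    """Enrichment of GWAS-haQTL-colocalized gAREs among predicted links.

    Compares the fraction of colocalized gAREs among gAREs with a
    predicted gene link against the fraction among all gAREs, by a
    one-sided two-sample proportion z-test (alternative: linked >
    background).  Returns ``(prop_linked, prop_background, p)``.
    """
    linked = set(linked_gares)
    universe = set(all_gares)
    if not linked:
        raise ValueError("empty linked set")
    if not linked <= universe:
        raise ValueError("linked gAREs must be a subset of all gAREs")
    flags = pd.Series(colocalized_flags)
    x1 = int(flags.reindex(list(linked)).fillna(False).sum())
    x2 = int(flags.reindex(list(universe)).fillna(False).sum())
    n1, n2 = len(linked), len(universe)
    _, p = proportions_ztest([x1, x2], [n1, n2], alternative="larger")
    return x1 / n1, x2 / n2, float(p)


def pp_ratio(pp4: float, pp3: float, cap: float = PP_RATIO_CAP) -> float:
    """PP4/PP3 with the ratio capped when PP3 underflows."""
    if pp3 <= 0:
        return cap
    return min(pp4 / pp3, cap)
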