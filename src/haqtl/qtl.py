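"""Cis-QTL mapping for ARE activity (and, reused, gene expression).

Covariate/latent-factor removal, nominal window scan by simple linear
regression, permutation-based empirical p-values with a Beta-distribution
approximation of the per-locus minimum-p null, and gARE/haQTL calling at
the empirical-p threshold with per-locus nominal thresholds.

The phenotype is residualized once against [covariates | top phenotype
PCs] and then scanned variant-by-variant; the regression degrees of
freedom are reduced by the number of removed covariate dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .synthetic import GenotypeMatrix

__all__ = [
    "residualize",
    "nominal_scan",
    "empirical_p",
    "call_gares",
    "map_qtls",
    "LocusResult",
    "QTLSet",
]

DEFAULT_WINDOW_BP = 100_000
DEFAULT_MAF_MIN = 0.05
DEFAULT_PERMUTATIONS = 1_000
GARE_EMPIRICAL_THRESHOLD = 0.005


@dataclass
class LocusResult:
    """Per-feature cis-QTL summary."""

    feature_id: str
    lead: pd.Series  # row of the nominal scan table
    n_variants_tested: int
    beta_shape1: float
    beta_shape2: float
    p_empirical: float
    p_empirical_direct: float
    nominal_threshold: float
    nominals: pd.DataFrame = field(repr=False, default=None)


@dataclass
class QTLSet:
    """Significant features (gAREs/eGenes) and their per-variant QTLs."""

    features: list[str]
    qtls: dict[str, pd.DataFrame]  # feature -> nominal rows passing threshold
    loci: dict[str, LocusResult]


def residualize(
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    n_latent_factors: int = 0,
) -> tuple[pd.DataFrame, int]:
    """Residualize phenotypes on known covariates plus top phenotype PCs.

    ``phenotypes`` is feature x sample; ``covariates`` is sample x
    covariate.  Latent factors are the top principal components of the
    (sample x feature) phenotype matrix, standing in for PEER factors.
    Returns ``(residuals, n_removed)`` where ``n_removed`` counts the
    non-intercept design columns (for downstream degree-of-freedom
    bookkeeping).  Residuals are orthogonal to the design.
    """
    Y = phenotypes.to_numpy(float).T  # samples x features
    n = Y.shape[0]
    cols = [np.ones((n, 1))]
    names = ["intercept"]
    if covariates is not None and covariates.shape[1]:
        if list(covariates.index) != list(phenotypes.columns):
            covariates = covariates.loc[phenotypes.columns]
        cols.append(covariates.to_numpy(float))
        names += list(covariates.columns)
    if n_latent_factors:
        pcs = PCA(n_components=n_latent_factors, svd_solver="full").fit_transform(
            Y - Y.mean(axis=0)
        )
        cols.append(pcs)
        names += [f"PC{i + 1}" for i in range(n_latent_factors)]
    D = np.hstack(cols)
    if D.shape[1] >= n:
        raise ValueError("more design columns than samples")
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        # name the collinear columns via pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(D, pivoting=True, mode="economic")
        dropped = [names[j] for j in piv[rank:]]
        raise ValueError(f"rank-deficient design; collinear columns: {dropped}")
    beta, *_ = np.linalg.lstsq(D, Y, rcond=None)
    resid = Y - D @ beta
    resid -= resid.mean(axis=0)  # re-center (no-op up to fp noise)
    out = pd.DataFrame(resid.T, index=phenotypes.index, columns=phenotypes.columns)
    return out, D.shape[1] - 1


def _scan_stats(
    y: np.ndarray, G: np.ndarray, dof: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized simple-regression stats of y on each row of G."""
    n = y.shape[0]
    yc = y - y.mean()
    Gc = G - G.mean(axis=1, keepdims=True)
    gss = (Gc**2).sum(axis=1)
    gss_safe = np.where(gss == 0, np.nan, gss)
    beta = (Gc @ yc) / gss_safe
    yss = (yc**2).sum()
    r2 = np.where(yss > 0, beta**2 * gss_safe / yss, 0.0)
    r2 = np.clip(r2, 0.0, 1.0 - 1e-15)
    t = np.sign(beta) * np.sqrt(r2 * dof / (1.0 - r2))
    se = np.abs(beta) / np.maximum(np.abs(t), 1e-300)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return beta, se, t, np.clip(p, 5e-324, 1.0)


def _window_variants(
    genotypes: GenotypeMatrix, center: int, window_bp: int, maf_min: float
) -> np.ndarray:
    maf = genotypes.maf()
    in_win = np.abs(genotypes.positions - center) <= window_bp
    return np.flatnonzero(in_win & (maf >= maf_min))


def nominal_scan(
    feature_id: str,
    center: int,
    residual_phenotype: pd.Series | np.ndarray,
    genotypes: GenotypeMatrix,
    window_bp: int = DEFAULT_WINDOW_BP,
    maf_min: float = DEFAULT_MAF_MIN,
    n_removed_covariates: int = 0,
) -> pd.DataFrame:
    """Per-variant simple-regression association within the cis window.

    Variants farther than ``window_bp`` from the feature center or with
    empirical MAF below ``maf_min`` are excluded.  Returns one row per
    tested variant (empty frame if the window is empty).
    """
    y = np.asarray(residual_phenotype, float)
    idx = _window_variants(genotypes, center, window_bp, maf_min)
    cols = [
        "feature_id", "variant_id", "beta", "se", "t_stat", "p_nominal",
        "distance_to_center", "maf",
    ]
    if idx.size == 0:
        return pd.DataFrame(columns=cols)
    dof = len(y) - 2 - n_removed_covariates
    if dof < 1:
        raise ValueError("not enough samples for the residual degrees of freedom")
    G = genotypes.dosages[idx]
    beta, se, t, p = _scan_stats(y, G, dof)
    maf = genotypes.maf()[idx]
    return pd.DataFrame(
        {
            "feature_id": feature_id,
            "variant_id": [genotypes.variant_ids[i] for i in idx],
            "beta": beta,
            "se": se,
            "t_stat": t,
            "p_nominal": p,
            "distance_to_center": genotypes.positions[idx] - center,
            "maf": maf,
        }
    )


def _fit_beta_mle(minp: np.ndarray) -> tuple[float, float]:
    """Beta(a, b) maximum-likelihood fit to permutation minimum p-values."""
    eps = 1e-300
    x = np.clip(minp, eps, 1.0 - 1e-12)
    try:
        a, b, _, _ = stats.beta.fit(x, floc=0.0, fscale=1.0)
    except Exception:  # fall back to method of moments
        m, v = x.mean(), max(x.var(), 1e-12)
        common = m * (1.0 - m) / v - 1.0
        a, b = m * common, (1.0 - m) * common
    a = float(np.clip(a, 1e-3, 1e6))
    b = float(np.clip(b, 1e-3, 1e6))
    return a, b


def _lead_row(nominals: pd.DataFrame) -> pd.Series:
    """Lead variant: smallest p, then smallest |distance|, then variant id."""
    d = nominals.assign(_absd=nominals["distance_to_center"].abs())
    d = d.sort_values(["p_nominal", "_absd", "variant_id"], kind="mergesort")
    return d.iloc[0].drop("_absd")


def empirical_p(
    feature_id: str,
    center: int,
    residual_phenotype: pd.Series | np.ndarray,
    genotypes: GenotypeMatrix,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    window_bp: int = DEFAULT_WINDOW_BP,
    maf_min: float = DEFAULT_MAF_MIN,
    n_removed_covariates: int = 0,
) -> LocusResult | None:
    """Permutation-based locus-level empirical p with a Beta approximation.

    The phenotype vector is permuted across samples ``n_permutations``
    times; the minimum nominal p over window variants is recorded per
    permutation and a Beta(a, b) is fitted to the minima by maximum
    likelihood.  The empirical p is the fitted Beta CDF at the observed
    lead p; the direct estimate (r + 1) / (n + 1) is reported alongside.
    Returns None when the window holds no testable variant.
    """
    y = np.asarray(residual_phenotype, float)
    if np.unique(y).size < 2:
        raise ValueError("phenotype is constant; cannot permute")
    nominals = nominal_scan(
        feature_id, center, y, genotypes, window_bp, maf_min, n_removed_covariates
    )
    if not len(nominals):
        return None
    lead = _lead_row(nominals)
    dof = len(y) - 2 - n_removed_covariates

    idx = _window_variants(genotypes, center, window_bp, maf_min)
    G = genotypes.dosages[idx]
    Gc = G - G.mean(axis=1, keepdims=True)
    gsd = np.sqrt((Gc**2).sum(axis=1))
    gsd[gsd == 0] = np.inf
    Gs = Gc / gsd[:, None]  # unit-norm rows

    rng = np.random.default_rng(seed)
    n = len(y)
    yc = y - y.mean()
    ynorm = np.sqrt((yc**2).sum())
    perms = np.empty((n_permutations, n))
    for i in range(n_permutations):
        perms[i] = yc[rng.permutation(n)]
    # max |corr| over variants per permutation <-> min p (same dof everywhere)
    corr = (perms @ Gs.T) / ynorm
    max_r2 = np.clip((corr**2).max(axis=1), 0.0, 1.0 - 1e-15)
    t_perm = np.sqrt(max_r2 * dof / (1.0 - max_r2))
    minp = np.clip(2.0 * stats.t.sf(t_perm, dof), 5e-324, 1.0)

    a, b = _fit_beta_mle(minp)
    p_lead = float(lead["p_nominal"])
    p_emp = float(np.clip(stats.beta.cdf(p_lead, a, b), 5e-324, 1.0))
    p_direct = (np.sum(minp <= p_lead) + 1.0) / (n_permutations + 1.0)
    return LocusResult(
        feature_id=feature_id,
        lead=lead,
        n_variants_tested=len(nominals),
        beta_shape1=a,
        beta_shape2=b,
        p_empirical=p_emp,
        p_empirical_direct=float(p_direct),
        nominal_threshold=float(
            stats.beta.ppf(GARE_EMPIRICAL_THRESHOLD, a, b)
        ),
        nominals=nominals,
    )


def call_gares(
    locus_results: list[LocusResult],
    empirical_threshold: float = GARE_EMPIRICAL_THRESHOLD,
) -> QTLSet:
    """Call gAREs/eGenes and their per-locus QTL variant lists.

    A feature is significant iff its Beta-approximated empirical p is at
    most ``empirical_threshold``; its QTLs are the window variants whose
    nominal p is at most the locus-specific nominal threshold, the
    inverse Beta CDF of the empirical threshold under the fitted shapes.
    """
    features: list[str] = []
    qtls: dict[str, pd.DataFrame] = {}
    loci: dict[str, LocusResult] = {}
    for lr in locus_results:
        if lr is None:
            continue
        loci[lr.feature_id] = lr
        if lr.p_empirical <= empirical_threshold:
            features.append(lr.feature_id)
            thr = stats.beta.ppf(empirical_threshold, lr.beta_shape1, lr.beta_shape2)
            qtls[lr.feature_id] = lr.nominals[
                lr.nominals["p_nominal"] <= thr
            ].reset_index(drop=True)
    return QTLSet(features=features, qtls=qtls, loci=loci)


def map_qtls(
    phenotypes: pd.DataFrame,
    feature_centers: pd.Series,
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame | None = None,
    n_latent_factors: int = 0,
    window_bp: int = DEFAULT_WINDOW_BP,
    maf_min: float = DEFAULT_MAF_MIN,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
) -> tuple[list[LocusResult], QTLSet]:
    """End-to-end cis-QTL mapping for one tissue.

    Residualizes the phenotype matrix once, then runs the permutation
    scheme per feature.  ``feature_centers`` maps feature id -> bp center
    of its cis window.
    """
    resid, n_removed = residualize(phenotypes, covariates, n_latent_factors)
    rng = np.random.default_rng(seed)
    results = []
    for feat in phenotypes.index:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        if feat not in feature_centers.index:
            continue
        lr = empirical_p(
            feat,
            int(feature_centers[feat]),
            resid.loc[feat].to_numpy(),
            genotypes,
            n_permutations=n_permutations,
            seed=sub_seed,
            window_bp=window_bp,
            maf_min=maf_min,
            n_removed_covariates=n_removed,
        )
        if lr is not None:
            results.append(lr)
    return results, call_gares(results)
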