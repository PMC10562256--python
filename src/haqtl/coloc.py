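"""Bayesian colocalization of two association signals (ABF / PP0-PP4).

Per-variant approximate Bayes factors follow Wakefield's asymptotic form,

    log ABF = 0.5 * log(1 - r) + 0.5 * z^2 * r,   r = W / (V + W),

with V the squared standard error and W the prior effect variance.
Posterior probabilities over the five single-causal-variant hypotheses
(H0: no association; H1/H2: one trait only; H3: distinct causal
variants; H4: shared causal variant) are accumulated in log space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "wakefield_abf",
    "coloc_posteriors",
    "classify_loci",
    "ColocPosterior",
    "DEFAULT_PRIORS",
    "PP4_COLOCALIZED",
    "PP4_EQTL_MISSING",
]

DEFAULT_PRIORS = {"p1": 1e-4, "p2": 1e-4, "p12": 1e-5}
PRIOR_SD_QUANTITATIVE = 0.15
PRIOR_SD_CASE_CONTROL = 0.2
PP4_COLOCALIZED = 0.5
PP4_EQTL_MISSING = 0.1

COLOCALIZED = "colocalized"
EQTL_MISSING = "bulk-eQTL-missing"
EQTL_CAPTURING = "bulk-eQTL-capturing"
NONE_LABEL = "none"


@dataclass
class ColocPosterior:
    pp: np.ndarray  # PP0..PP4
    priors: dict[str, float]

    def __getitem__(self, i: int) -> float:
        return float(self.pp[i])

    @property
    def pp4(self) -> float:
        return float(self.pp[4])

    @property
    def pp3(self) -> float:
        return float(self.pp[3])


def wakefield_abf(
    assoc: pd.DataFrame, prior_sd: float | None = None
) -> pd.DataFrame:
    """Per-variant log approximate Bayes factors.

    ``assoc`` needs ``variant_id`` plus either ``z`` or ``beta``/``se``;
    a ``trait_type`` column ('quantitative' or 'case-control') selects
    the default prior sd when ``prior_sd`` is None.  Returns a frame
    with ``variant_id, log_abf, r``.
    """
    if "se" not in assoc.columns or assoc["se"].isna().any():
        raise ValueError("standard errors required for every variant")
    if (assoc["se"] <= 0).any():
        raise ValueError("standard errors must be positive")
    if prior_sd is None:
        tt = assoc["trait_type"].iloc[0] if "trait_type" in assoc.columns else "quantitative"
        prior_sd = (
            PRIOR_SD_CASE_CONTROL if tt == "case-control" else PRIOR_SD_QUANTITATIVE
        )
    V = assoc["se"].to_numpy(float) ** 2
    z = (
        assoc["z"].to_numpy(float)
        if "z" in assoc.columns
        else assoc["beta"].to_numpy(float) / assoc["se"].to_numpy(float)
    )
    W = prior_sd**2
    r = W / (V + W)
    log_abf = 0.5 * np.log1p(-r) + 0.5 * z**2 * r
    return pd.DataFrame(
        {"variant_id": assoc["variant_id"].to_numpy(), "log_abf": log_abf, "r": r}
    )


def _log_diff_exp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a > b, stable for close values."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def coloc_posteriors(
    abf1: pd.DataFrame,
    abf2: pd.DataFrame,
    p1: float = DEFAULT_PRIORS["p1"],
    p2: float = DEFAULT_PRIORS["p2"],
    p12: float = DEFAULT_PRIORS["p12"],
) -> ColocPosterior:
    """PP0-PP4 over the shared variant set of two ABF vectors.

    Hypothesis sums are taken over all single-causal-variant
    configurations in log space: H1 = sum_i ABF1_i, H2 = sum_j ABF2_j,
    H3 = sum_{i != j} ABF1_i ABF2_j, H4 = sum_i ABF1_i ABF2_i, each
    weighted by its prior; the five terms are normalized to posteriors.
    """
    merged = abf1.merge(abf2, on="variant_id", suffixes=("_1", "_2"))
    if not len(merged):
        raise ValueError("no shared variants between the two traits")
    if len(merged) < 10:
        warnings.warn(f"only {len(merged)} shared variants; posteriors unstable")
    l1 = merged["log_abf_1"].to_numpy(float)
    l2 = merged["log_abf_2"].to_numpy(float)

    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    lH0 = 0.0
    lH1 = np.log(p1) + s1
    lH2 = np.log(p2) + s2
    lH3 = np.log(p1) + np.log(p2) + _log_diff_exp(s1 + s2, s12)
    lH4 = np.log(p12) + s12
    terms = np.array([lH0, lH1, lH2, lH3, lH4])
    pp = np.exp(terms - logsumexp(terms))
    pp /= pp.sum()
    return ColocPosterior(pp=pp, priors={"p1": p1, "p2": p2, "p12": p12})


def classify_loci(
    gwas_haqtl_posterior: ColocPosterior,
    gwas_eqtl_posteriors: dict[str, ColocPosterior] | None = None,
    pp4_colocalized: float = PP4_COLOCALIZED,
    pp4_eqtl_missing: float = PP4_EQTL_MISSING,
) -> dict:
    """Classify a GWAS-haQTL locus and its eQTL backup.

    Colocalized iff GWAS-haQTL PP4 >= 0.5; among colocalized loci,
    bulk-eQTL-missing iff the best GWAS-eQTL PP4 over candidate genes is
    below 0.1, else bulk-eQTL-capturing.
    """
    pp4 = gwas_haqtl_posterior.pp4
    eqtl_pp4 = {
        g: p.pp4 for g, p in (gwas_eqtl_posteriors or {}).items()
    }
    if pp4 >= pp4_colocalized:
        best = max(eqtl_pp4.values()) if eqtl_pp4 else 0.0
        label = EQTL_MISSING if best < pp4_eqtl_missing else EQTL_CAPTURING
    else:
        label = NONE_LABEL
    return {
        "gwas_haqtl_pp4": pp4,
        "eqtl_pp4_by_gene": eqtl_pp4,
        "colocalized": pp4 >= pp4_colocalized,
        "label": label,
    }
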