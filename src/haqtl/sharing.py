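"""Cross-tissue sharing of ARE genetic regulation.

Lead haQTLs significant in a discovery tissue are paired with their
association statistics in a replication tissue, binned by replication
p-value, and summarized by directionality consistency (DC): the fraction
of pairs whose effect sign agrees across tissues.  The sharing proportion
is

    sharing = sum_i Perc_i * (2 * DC_i - 1)

over the four replication bins; gAREs are classified into type I
(haQTL-shared), II (haQTL-specific) and III (ARE-specific).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "pair_leads",
    "consistency_by_bin",
    "sharing_proportion",
    "effect_similarity",
    "classify_gare_types",
    "ConsistencyBins",
    "SharingEstimate",
    "REPLICATION_P_THRESHOLD",
]

# replication p-value bin edges: strong / medium / weak / no-effect
BIN_EDGES = (1e-5, 1e-3, 0.1)
BIN_NAMES = ("strong", "medium", "weak", "no-effect")
REPLICATION_P_THRESHOLD = 0.02

TYPE_I = "I haQTL-shared"
TYPE_II = "II haQTL-specific"
TYPE_III = "III ARE-specific"


@dataclass
class ConsistencyBins:
    table: pd.DataFrame  # index: bin name; columns: count, perc, dc


@dataclass
class SharingEstimate:
    discovery_tissue: str
    replication_tissue: str
    sharing: float  # clamped to [0, 1] for reporting
    sharing_raw: float  # signed value in [-1, 1]
    bins: ConsistencyBins


def pair_leads(
    discovery_leads: pd.DataFrame,
    replication_nominals: pd.DataFrame,
    are_presence: pd.DataFrame | None = None,
    discovery_tissue: str = "discovery",
    replication_tissue: str = "replication",
) -> pd.DataFrame:
    """Attach replication statistics to discovery lead haQTLs.

    ``discovery_leads`` needs ``feature_id, variant_id, beta, p_nominal``;
    ``replication_nominals`` is the replication tissue's nominal scan
    table with the same columns.  Leads whose ARE is absent in the
    replication tissue (per ``are_presence``) or whose variant was not
    tested there are excluded — absent AREs are type-III territory.
    """
    rep = replication_nominals.set_index(["feature_id", "variant_id"])
    rows = []
    for r in discovery_leads.itertuples():
        if are_presence is not None:
            if (
                r.feature_id in are_presence.index
                and replication_tissue in are_presence.columns
                and not bool(are_presence.loc[r.feature_id, replication_tissue])
            ):
                continue
        key = (r.feature_id, r.variant_id)
        if key not in rep.index:
            continue
        rr = rep.loc[key]
        rows.append(
            {
                "gare_id": r.feature_id,
                "variant_id": r.variant_id,
                "beta_discovery": r.beta,
                "p_discovery": r.p_nominal,
                "beta_replication": rr["beta"],
                "p_replication": rr["p_nominal"],
                "discovery_tissue": discovery_tissue,
                "replication_tissue": replication_tissue,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gare_id", "variant_id", "beta_discovery", "p_discovery",
            "beta_replication", "p_replication", "discovery_tissue",
            "replication_tissue",
        ],
    )


def _bin_index(p: np.ndarray) -> np.ndarray:
    e1, e2, e3 = BIN_EDGES
    return np.select([p < e1, p < e2, p < e3], [0, 1, 2], default=3)


def consistency_by_bin(pairs: pd.DataFrame) -> ConsistencyBins:
    """Directionality consistency per replication-p bin.

    Pairs with a zero effect size on either side are dropped with a
    warning (sign undefined).  DC is NaN for empty bins; Perc sums to 1
    over non-empty bins.
    """
    if not len(pairs):
        raise ValueError("no pairs given")
    zero = (pairs["beta_discovery"] == 0) | (pairs["beta_replication"] == 0)
    if zero.any():
        warnings.warn(f"dropping {int(zero.sum())} pairs with zero effect size")
        pairs = pairs[~zero]
    if not len(pairs):
        raise ValueError("all pairs had zero effect sizes")
    b = _bin_index(pairs["p_replication"].to_numpy(float))
    same = np.sign(pairs["beta_discovery"].to_numpy()) == np.sign(
        pairs["beta_replication"].to_numpy()
    )
    rows = []
    for i, name in enumerate(BIN_NAMES):
        mask = b == i
        cnt = int(mask.sum())
        rows.append(
            {
                "bin": name,
                "count": cnt,
                "perc": cnt / len(pairs),
                "dc": float(same[mask].mean()) if cnt else np.nan,
            }
        )
    return ConsistencyBins(table=pd.DataFrame(rows).set_index("bin"))


def sharing_proportion(
    bins: ConsistencyBins,
    discovery_tissue: str = "discovery",
    replication_tissue: str = "replication",
) -> SharingEstimate:
    """Tissue-sharing = sum_i Perc_i * (2 DC_i - 1); empty bins contribute 0."""
    t = bins.table
    perc = t["perc"].to_numpy(float)
    dc = t["dc"].to_numpy(float)
    contrib = np.where(np.isnan(dc), 0.0, perc * (2.0 * np.nan_to_num(dc) - 1.0))
    raw = float(contrib.sum())
    return SharingEstimate(
        discovery_tissue=discovery_tissue,
        replication_tissue=replication_tissue,
        sharing=float(np.clip(raw, 0.0, 1.0)),
        sharing_raw=raw,
        bins=bins,
    )


def effect_similarity(pairs: pd.DataFrame, bin_name: str | None = None) -> float:
    """OLS slope (intercept included) of replication beta on discovery beta."""
    if bin_name is not None:
        idx = _bin_index(pairs["p_replication"].to_numpy(float))
        pairs = pairs[idx == BIN_NAMES.index(bin_name)]
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    x = pairs["beta_discovery"].to_numpy(float)
    y = pairs["beta_replication"].to_numpy(float)
    if np.var(x) == 0:
        raise ValueError("zero variance in discovery effect sizes")
    return float(stats.linregress(x, y).slope)


def classify_gare_types(
    gares_per_tissue: dict[str, list[str]],
    are_presence: pd.DataFrame,
    replication_p: dict[tuple[str, str, str], float],
    p_share_threshold: float = REPLICATION_P_THRESHOLD,
) -> pd.DataFrame:
    """Label each (gARE, discovery tissue) as type I, II or III.

    ``replication_p[(gare, discovery, replication)]`` holds the lead
    haQTL's nominal p in the replication tissue.  Rules: ARE absent from
    every other tissue -> III (ARE-specific); present elsewhere with
    replication p <= threshold in >= 1 other tissue -> I (haQTL-shared);
    present elsewhere but never replicating -> II (haQTL-specific).
    """
    tissues = sorted(gares_per_tissue)
    rows = []
    for tis in tissues:
        for gare in gares_per_tissue[tis]:
            others = [t for t in are_presence.columns if t != tis]
            present_elsewhere = (
                bool(are_presence.loc[gare, others].any())
                if gare in are_presence.index
                else False
            )
            if not present_elsewhere:
                label = TYPE_III
            else:
                reps = [
                    replication_p.get((gare, tis, t2), np.nan) for t2 in others
                ]
                reps = [p for p in reps if not np.isnan(p)]
                label = (
                    TYPE_I
                    if any(p <= p_share_threshold for p in reps)
                    else TYPE_II
                )
            rows.append({"gare_id": gare, "tissue": tis, "label": label})
    return pd.DataFrame(rows, columns=["gare_id", "tissue", "label"])
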