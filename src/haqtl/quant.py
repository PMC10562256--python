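"""Active-regulatory-element (ARE) quantification.

Candidate H3K27ac peak filtering, cross-tissue reference merging,
fragment-based activity quantification and depth normalization.

Intervals are BED-style throughout: 0-based, half-open ``[start, end)``.
Interval tables are pandas DataFrames with at least the columns
``chrom``, ``start``, ``end``; extra columns (``sample``, ``qvalue``,
``are_id`` ...) ride along.  Interval algebra is delegated to pyranges.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pyranges as pr

__all__ = [
    "filter_candidate_peaks",
    "merge_reference_ares",
    "quantify_activity",
    "size_factor_normalize",
    "gc_correct",
]

_BED_COLS = ["chrom", "start", "end"]


def _check_intervals(df: pd.DataFrame, name: str = "intervals") -> pd.DataFrame:
    missing = [c for c in _BED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{name}: missing columns {missing}")
    if len(df) and not (df["start"] < df["end"]).all():
        bad = df.index[df["start"] >= df["end"]].tolist()[:5]
        raise ValueError(f"{name}: start >= end at rows {bad}")
    if len(df) and (df["start"] < 0).any():
        raise ValueError(f"{name}: negative start coordinates")
    return df


def _to_pr(df: pd.DataFrame, extra: list[str] | None = None) -> pr.PyRanges:
    cols = {"chrom": "Chromosome", "start": "Start", "end": "End"}
    keep = _BED_COLS + (extra or [])
    return pr.PyRanges(df[keep].rename(columns=cols))


def _from_pr(g: pr.PyRanges) -> pd.DataFrame:
    df = g.df if len(g) else pd.DataFrame(columns=["Chromosome", "Start", "End"])
    return df.rename(columns={"Chromosome": "chrom", "Start": "start", "End": "end"})


def filter_candidate_peaks(
    per_sample_peaks: pd.DataFrame,
    tier1_flags: dict[str, bool],
    reference_peaks: pd.DataFrame | None,
    state_intervals: pd.DataFrame | None,
    q_threshold: float = 0.01,
    min_tier1_samples: int = 2,
    min_state_overlap: int = 50,
) -> pd.DataFrame:
    """Filter per-sample peak calls down to the tissue ARE candidate set.

    A peak survives if it has q-value <= ``q_threshold`` and overlaps
    (>= 1 bp) peaks from at least ``min_tier1_samples`` distinct Tier-1
    samples, *or* if it overlaps a tissue-matched reference peak (the
    reference rescue ignores the q-value).  Surviving peaks must then
    overlap a promoter/enhancer chromatin-state interval by at least
    ``min_state_overlap`` bp.

    Parameters
    ----------
    per_sample_peaks
        Columns ``chrom, start, end, sample, qvalue``.
    tier1_flags
        Sample id -> whether the sample is Tier 1; must cover every
        sample present in ``per_sample_peaks``.
    reference_peaks, state_intervals
        BED-style frames; either may be None/empty (no rescue / no
        state filtering).
    """
    peaks = _check_intervals(per_sample_peaks.reset_index(drop=True), "peaks")
    if "qvalue" not in peaks.columns or peaks["qvalue"].isna().any():
        raise ValueError("peaks: q-values required for every peak")
    if "sample" not in peaks.columns:
        raise ValueError("peaks: 'sample' column required")
    unknown = set(peaks["sample"]) - set(tier1_flags)
    if unknown:
        raise ValueError(f"tier1_flags missing for samples {sorted(unknown)}")

    peaks = peaks.copy()
    peaks["_pid"] = np.arange(len(peaks))

    tier1_samples = {s for s, f in tier1_flags.items() if f}
    t1 = peaks[peaks["sample"].isin(tier1_samples)]
    support = pd.Series(0, index=peaks["_pid"])
    if len(t1):
        j = _to_pr(peaks.rename(columns={"_pid": "pid"}), ["pid"]).join(
            _to_pr(t1.rename(columns={"sample": "t1_sample"}), ["t1_sample"])
        )
        if len(j):
            counts = j.df.groupby("pid")["t1_sample"].nunique()
            support.loc[counts.index] = counts.values

    qual = (peaks["qvalue"].to_numpy() <= q_threshold) & (
        support.to_numpy() >= min_tier1_samples
    )

    rescued = np.zeros(len(peaks), dtype=bool)
    if reference_peaks is not None and len(reference_peaks):
        _check_intervals(reference_peaks, "reference_peaks")
        j = _to_pr(peaks.rename(columns={"_pid": "pid"}), ["pid"]).join(
            _to_pr(reference_peaks)
        )
        if len(j):
            rescued[np.unique(j.df["pid"].to_numpy())] = True

    kept = peaks[qual | rescued]

    if state_intervals is not None and len(state_intervals):
        _check_intervals(state_intervals, "state_intervals")
        j = _to_pr(kept.rename(columns={"_pid": "pid"}), ["pid"]).join(
            _to_pr(state_intervals)
        )
        ok: set[int] = set()
        if len(j):
            jd = j.df
            ov = np.minimum(jd["End"], jd["End_b"]) - np.maximum(
                jd["Start"], jd["Start_b"]
            )
            ok = set(jd.loc[ov >= min_state_overlap, "pid"])
        kept = kept[kept["_pid"].isin(ok)]

    return kept.drop(columns="_pid").reset_index(drop=True)


def merge_reference_ares(
    per_tissue_are_sets: dict[str, pd.DataFrame],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge per-tissue ARE sets into a reference set plus presence matrix.

    Overlapping or bookended intervals across tissues are merged into
    maximal intervals.  Returns ``(reference, presence)`` where
    ``reference`` has columns ``chrom, start, end, are_id`` and
    ``presence`` is an ARE x tissue boolean DataFrame marking each
    tissue contributing >= 1 bp of overlap to the merged ARE.
    """
    if not per_tissue_are_sets:
        raise ValueError("no tissue ARE sets given")
    frames = []
    for tissue, df in per_tissue_are_sets.items():
        d = _check_intervals(df, f"ares[{tissue}]")[_BED_COLS].copy()
        d["tissue"] = tissue
        frames.append(d)
    allp = pd.concat(frames, ignore_index=True)
    merged = _from_pr(_to_pr(allp).merge(slack=0))
    merged = merged.sort_values(["chrom", "start"]).reset_index(drop=True)
    merged["are_id"] = [
        f"{c}:{s}-{e}" for c, s, e in zip(merged["chrom"], merged["start"], merged["end"])
    ]

    tissues = list(per_tissue_are_sets)
    presence = pd.DataFrame(False, index=merged["are_id"], columns=tissues)
    j = _to_pr(merged, ["are_id"]).join(_to_pr(allp, ["tissue"]))
    if len(j):
        for (are, tis), _ in j.df.groupby(["are_id", "tissue"]):
            presence.loc[are, tis] = True
    return merged, presence


def quantify_activity(fragments: pd.DataFrame, ares: pd.DataFrame) -> pd.DataFrame:
    """Per-ARE, per-sample activity = sum of fragment overlap / ARE length.

    ``fragments`` needs ``chrom, start, end, sample``; ``ares`` needs
    ``chrom, start, end, are_id``.  Returns an ARE x sample DataFrame
    (``.attrs['normalized'] = False``); fragments overlapping no ARE
    contribute nothing, samples with no fragments get zero columns.
    """
    if ares is None or not len(ares):
        raise ValueError("empty ARE set")
    _check_intervals(ares, "ares")
    _check_intervals(fragments, "fragments")
    if "sample" not in fragments.columns:
        raise ValueError("fragments: 'sample' column required")

    are_ids = list(ares["are_id"])
    samples = sorted(fragments["sample"].unique())
    lengths = (ares["end"] - ares["start"]).to_numpy(float)
    out = pd.DataFrame(0.0, index=pd.Index(are_ids, name="are_id"), columns=samples)

    if len(fragments):
        j = _to_pr(ares, ["are_id"]).join(_to_pr(fragments, ["sample"]))
        if len(j):
            jd = j.df
            jd["ov"] = np.minimum(jd["End"], jd["End_b"]) - np.maximum(
                jd["Start"], jd["Start_b"]
            )
            tot = jd.groupby(["are_id", "sample"])["ov"].sum().unstack(fill_value=0.0)
            out.loc[tot.index, tot.columns] += tot
    out = out.div(pd.Series(lengths, index=out.index), axis=0)
    out.attrs["normalized"] = False
    return out


def size_factor_normalize(raw: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Median-of-ratios (DESeq2-style) depth normalization.

    For each sample k the factor is the median over AREs i with an
    all-positive row of ``raw[i, k] / geomean_i(raw[i, :])``; factors
    are then rescaled to geometric mean 1 and divided out.

    Returns ``(normalized, factors)``.
    """
    if raw.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    vals = raw.to_numpy(float)
    pos = (vals > 0).all(axis=1)
    if not pos.any():
        raise ValueError(
            "no ARE row is positive in every sample; add a pseudo-count or "
            "filter AREs before normalizing"
        )
    v = vals[pos]
    geomean = np.exp(np.log(v).mean(axis=1, keepdims=True))
    factors = np.median(v / geomean, axis=0)
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean -> 1
    normalized = raw.div(pd.Series(factors, index=raw.columns), axis=1)
    normalized.attrs["normalized"] = True
    return normalized, pd.Series(factors, index=raw.columns, name="size_factor")


def gc_correct(
    matrix: pd.DataFrame, gc_per_are: pd.Series, n_bins: int = 10
) -> pd.DataFrame:
    """Equalize per-sample activity medians within GC-content quantile bins.

    Within each GC bin b, sample k's values are scaled by
    ``median(bin b across all samples) / median(bin b in sample k)``,
    removing monotone GC artifacts.  Zero-median (all-zero) sample bins
    are left unscaled.
    """
    gc = gc_per_are.reindex(matrix.index)
    if gc.isna().any():
        raise ValueError("gc_per_are missing values for some AREs")
    if ((gc < 0) | (gc > 1)).any():
        raise ValueError("GC content must lie in [0, 1]")
    try:
        bins = pd.qcut(gc, q=n_bins, labels=False, duplicates="drop")
    except ValueError:  # constant gc -> single bin
        bins = pd.Series(0, index=gc.index)
    out = matrix.copy().astype(float)
    for _, idx in out.groupby(bins.values).groups.items():
        block = out.loc[idx]
        target = np.median(block.to_numpy())
        med = block.median(axis=0)
        scale = np.where(med > 0, target / med.replace(0, np.nan), 1.0)
        out.loc[idx] = block * np.nan_to_num(scale, nan=1.0)
    out.attrs["normalized"] = matrix.attrs.get("normalized", False)
    return out
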