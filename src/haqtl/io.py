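"""Plain-text readers/writers for the pipeline's standard formats.

BED for intervals and fragments (tab-separated, 0-based half-open),
TSV for matrices (header row = sample ids, index = feature ids) and
dosages, JSON for ground truth and manifests.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = [
    "read_bed",
    "write_bed",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "write_json",
]


def read_bed(path: str | Path, extra_cols: list[str] | None = None) -> pd.DataFrame:
    """Read a BED-style TSV; first three columns are chrom/start/end."""
    names = ["chrom", "start", "end"] + (extra_cols or [])
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(names)]
    df.columns = names[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path: str | Path, cols: list[str] | None = None) -> None:
    cols = cols or list(df.columns)
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_dosage_tsv(path: str | Path) -> pd.DataFrame:
    """Dosage TSV: rows = variants, columns = individuals, values in [0, 2]."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_dosage_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")


def _default(o):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
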