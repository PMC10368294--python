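"""Plain-text table I/O: count TSVs, metadata, DE results."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .stats import CountMatrix

__all__ = [
    "write_counts",
    "read_counts",
    "write_metadata",
    "read_metadata",
    "write_de",
]


def write_counts(cm: CountMatrix, path) -> None:
    cm.counts.rename_axis("gene_id").to_csv(path, sep="\t")


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.rename_axis("sample_id").to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def read_counts(path, metadata_path=None) -> CountMatrix:
    counts = pd.read_csv(path, sep="\t", index_col="gene_id")
    meta = None
    if metadata_path is not None and Path(metadata_path).exists():
        meta = read_metadata(metadata_path).loc[list(counts.columns)]
    return CountMatrix(counts, meta)


def write_de(de: pd.DataFrame, path) -> None:
    de.rename_axis("gene_id").to_csv(path, sep="\t", float_format="%.6g")
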