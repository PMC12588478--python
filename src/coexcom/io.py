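"""Readers and writers for the package's plain-text file dialects.

Expression matrices travel as TSV with genes as rows (first column
``gene_id``) and samples as columns; sample metadata as TSV with columns
``sample_id``, ``class`` and ``batch``.  Both are held in memory as pandas
DataFrames: expression indexed by gene id with sample-id columns, metadata
indexed by sample id.
"""

from __future__ import annotations

import pandas as pd

CLASS_LABELS = ("case", "control")


def validate_expression(matrix: pd.DataFrame) -> None:
    """Check the expression-matrix invariants: unique ids, no missing values."""
    if matrix.index.duplicated().any():
        dup = matrix.index[matrix.index.duplicated()][0]
        raise ValueError(f"duplicated gene_id: {dup!r}")
    if matrix.columns.duplicated().any():
        dup = matrix.columns[matrix.columns.duplicated()][0]
        raise ValueError(f"duplicated sample_id: {dup!r}")
    if matrix.isna().any().any():
        raise ValueError("expression matrix contains missing values")


def validate_metadata(metadata: pd.DataFrame, sample_ids=None) -> None:
    """Check metadata invariants: class labels, one row per matrix sample."""
    for col in ("class", "batch"):
        if col not in metadata.columns:
            raise ValueError(f"metadata is missing required column {col!r}")
    bad = set(metadata["class"]) - set(CLASS_LABELS)
    if bad:
        raise ValueError(f"unknown class labels {sorted(bad)}; expected {CLASS_LABELS}")
    if metadata.index.duplicated().any():
        dup = metadata.index[metadata.index.duplicated()][0]
        raise ValueError(f"duplicated sample_id in metadata: {dup!r}")
    if sample_ids is not None:
        missing = set(sample_ids) - set(metadata.index)
        if missing:
            raise ValueError(f"metadata lacks samples: {sorted(missing)[:5]}")


def read_expression(path) -> pd.DataFrame:
    matrix = pd.read_csv(path, sep="\t", index_col="gene_id",
                         float_precision="round_trip")
    matrix.index = matrix.index.astype(str)
    matrix.columns = matrix.columns.astype(str)
    validate_expression(matrix)
    return matrix.astype(float)


def write_expression(matrix: pd.DataFrame, path) -> None:
    validate_expression(matrix)
    # %.17g round-trips IEEE doubles exactly
    matrix.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col="sample_id", dtype=str)
    validate_metadata(meta)
    return meta


def write_metadata(metadata: pd.DataFrame, path) -> None:
    validate_metadata(metadata)
    metadata.to_csv(path, sep="\t", index_label="sample_id")
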