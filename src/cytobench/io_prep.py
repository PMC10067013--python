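"""Reading and writing expression matrices, embeddings, labels and scores.

Delimited inputs follow common CyTOF CSV exports: a header row of marker
names, one row per cell. FCS 3.0/3.1 files are read through the built-in
minimal parser. Preprocessing is limited to the standard arcsinh
transform; inputs are assumed to be pre-gated (debris removal and bead
normalization are instrument-pipeline steps outside this package).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from ._fcs import read_fcs, write_fcs
from ._types import Embedding, ExpressionMatrix, LabelVector

NA_TOKEN = "NA"

__all__ = [
    "read_expression",
    "write_expression",
    "write_fcs_file",
    "arcsinh_transform",
    "read_embedding",
    "write_embedding",
    "read_labels",
    "write_labels",
    "write_scores",
    "read_scores",
    "NA_TOKEN",
]


def read_expression(
    path: str,
    format: str = "delimited",
    channels: list[str] | None = None,
) -> ExpressionMatrix:
    """Read a cells x markers matrix from a delimited text file or FCS file.

    Parameters
    ----------
    path
        Input file.
    format
        ``"delimited"`` (CSV/TSV with a header row of marker names) or
        ``"fcs"``.
    channels
        Optional subset of marker names to retain, in the given order.
        All channels are kept when omitted.
    """
    if format == "delimited":
        sep = "\t" if path.endswith((".tsv", ".tab", ".txt")) else ","
        df = pd.read_csv(path, sep=sep)
        names = [str(c) for c in df.columns]
        values = df.to_numpy(dtype=float)
    elif format == "fcs":
        values, names = read_fcs(path)
    else:
        raise ValueError(f"unknown format {format!r}")

    if channels is not None:
        missing = [c for c in channels if c not in names]
        if missing:
            raise KeyError(f"requested channels not in file: {missing}")
        idx = [names.index(c) for c in channels]
        values = values[:, idx]
        names = list(channels)
    return ExpressionMatrix(values=values, marker_names=names)


def write_expression(X: ExpressionMatrix, path: str) -> None:
    """Write an expression matrix as CSV with a marker-name header."""
    pd.DataFrame(X.values, columns=X.marker_names).to_csv(path, index=False)


def write_fcs_file(X: ExpressionMatrix, path: str) -> None:
    """Write an expression matrix as a single-dataset FCS 3.1 file."""
    write_fcs(path, X.values, X.marker_names)


def arcsinh_transform(X: ExpressionMatrix, cofactor: float = 5.0) -> ExpressionMatrix:
    """Apply the standard cytometry variance-stabilizing transform.

    Each entry x becomes ``asinh(x / cofactor)``. The default cofactor of
    5 is the established convention for mass cytometry ion counts (flow
    cytometry typically uses 150).
    """
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    return ExpressionMatrix(
        values=np.arcsinh(X.values / cofactor),
        marker_names=list(X.marker_names),
        cell_ids=list(X.cell_ids) if X.cell_ids is not None else None,
    )


def read_embedding(path: str) -> Embedding:
    df = pd.read_csv(path)
    return Embedding(coords=df.to_numpy(dtype=float))


def write_embedding(emb: Embedding, path: str) -> None:
    pd.DataFrame(emb.coords, columns=["dim1", "dim2"]).to_csv(path, index=False)


def read_labels(path: str) -> LabelVector:
    df = pd.read_csv(path)
    return LabelVector(labels=df.iloc[:, 0].to_numpy())


def write_labels(labels: LabelVector, path: str, name: str = "label") -> None:
    pd.DataFrame({name: labels.labels}).to_csv(path, index=False)


def write_scores(table, path: str) -> None:
    """Serialize a ScoreTable or RankTable as TSV, failures as ``NA``.

    Rows are methods, columns metrics (plus category/overall columns for
    rank tables). The frame representation is delegated to the table's
    own ``to_frame``.
    """
    df = table.to_frame()
    if df.empty:
        raise ValueError("refusing to write an empty score table")
    df.to_csv(path, sep="\t", na_rep=NA_TOKEN, index_label="method")


def read_scores(path: str) -> pd.DataFrame:
    """Read back a table written by :func:`write_scores` (NA -> NaN)."""
    return pd.read_csv(
        path, sep="\t", index_col="method", na_values=[NA_TOKEN], keep_default_na=False
    )


def _ensure_dir(path: str) -> None:
    d = os.path.dirname(os.path.abspath(path))
    os.makedirs(d, exist_ok=True)
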