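"""Core in-memory containers shared across the package.

CyTOF data live in two spaces: the original marker space (an
:class:`ExpressionMatrix`, cells x protein markers, usually on the
arcsinh scale) and the reduced space (an :class:`Embedding`, cells x 2,
produced by some dimension-reduction back-end). Cluster or cell-type
assignments travel alongside as a :class:`LabelVector`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ExpressionMatrix", "Embedding", "LabelVector", "as_matrix", "as_labels"]


@dataclass
class ExpressionMatrix:
    """Cells x markers expression matrix with named marker channels.

    Parameters
    ----------
    values
        Real-valued matrix, one row per cell event, one column per
        protein marker. All entries must be finite.
    marker_names
        Unique channel names, one per column.
    cell_ids
        Optional per-cell identifiers (row names).
    """

    values: np.ndarray
    marker_names: list[str]
    cell_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n, m = self.values.shape
        if n < 1 or m < 1:
            raise ValueError("expression matrix needs at least 1 cell and 1 marker")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite entries")
        self.marker_names = [str(x) for x in self.marker_names]
        if len(self.marker_names) != m:
            raise ValueError("marker_names length does not match column count")
        if len(set(self.marker_names)) != m:
            raise ValueError("marker_names must be unique")
        if self.cell_ids is not None and len(self.cell_ids) != n:
            raise ValueError("cell_ids length does not match row count")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]


@dataclass
class Embedding:
    """A 2-D embedding, row-aligned with its source expression matrix."""

    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("embedding must be a cells x 2 matrix")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding contains non-finite entries")

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]


@dataclass
class LabelVector:
    """Categorical per-cell labels (cluster ids or cell-type names)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 1 or self.labels.size < 1:
            raise ValueError("labels must be a non-empty 1-D vector")

    def __len__(self) -> int:
        return int(self.labels.size)

    @property
    def categories(self) -> np.ndarray:
        return np.unique(self.labels)


def as_matrix(x) -> np.ndarray:
    """Coerce an ExpressionMatrix / Embedding / array-like to an ndarray."""
    if isinstance(x, ExpressionMatrix):
        return x.values
    if isinstance(x, Embedding):
        return x.coords
    return np.asarray(x, dtype=float)


def as_labels(x) -> np.ndarray:
    """Coerce a LabelVector / array-like to a 1-D label array."""
    if isinstance(x, LabelVector):
        return x.labels
    return np.asarray(x)
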