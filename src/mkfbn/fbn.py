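"""Pearson functional brain network estimation and proportional thresholding.

A subject's functional brain network is the region-by-region Pearson
correlation matrix of their ROI time series.  For graph analysis the
weighted network is binarized over a grid of proportional sparsity
thresholds: at sparsity ``s`` exactly ``round(s * n(n-1)/2)`` of the
strongest edges are retained, so the graphs along the grid are nested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConnectivityMatrix",
    "SparsityGrid",
    "BinaryGraphStack",
    "pearson_fbn",
    "binarize_at_sparsity",
    "threshold_stack",
]


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric unit-diagonal correlation matrix for one subject."""

    values: np.ndarray
    region_names: tuple[str, ...]
    subject_id: str = ""

    def __post_init__(self) -> None:
        W = self.values
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError(f"connectivity matrix must be square, got {W.shape}")
        if len(self.region_names) != W.shape[0]:
            raise ValueError("region_names length does not match matrix size")
        if np.abs(W - W.T).max() > 1e-12:
            raise ValueError("connectivity matrix is not symmetric to 1e-12")
        if np.any(np.diag(W) != 1.0):
            raise ValueError("connectivity matrix diagonal must be exactly 1")
        if np.abs(W).max() > 1.0:
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class SparsityGrid:
    """Evenly spaced proportional thresholds (defaults: 0.02..0.50 step 0.01)."""

    start: float = 0.02
    stop: float = 0.50
    step: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 < self.start <= self.stop < 1.0):
            raise ValueError(
                f"require 0 < start <= stop < 1, got start={self.start} stop={self.stop}"
            )
        if self.step <= 0:
            raise ValueError(f"step must be > 0, got {self.step}")

    def __len__(self) -> int:
        return round((self.stop - self.start) / self.step) + 1

    @property
    def values(self) -> np.ndarray:
        return np.round(self.start + self.step * np.arange(len(self)), 12)


@dataclass(frozen=True)
class BinaryGraphStack:
    """Per-threshold binary adjacency matrices for one subject (nested)."""

    thresholds: np.ndarray
    graphs: tuple[np.ndarray, ...]
    subject_id: str = ""

    def __len__(self) -> int:
        return len(self.graphs)


def pearson_fbn(
    series: np.ndarray,
    region_names: tuple[str, ...] | None = None,
    subject_id: str = "",
) -> ConnectivityMatrix:
    """Pearson correlation network from a timepoints-by-regions matrix.

    ``W[i, j]`` is the centered inner product of the two regional series
    normalized by the product of their centered norms; the diagonal is
    set to exactly 1.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError(f"series must be 2-D, got shape {series.shape}")
    t, n = series.shape
    if t < 3:
        raise ValueError(f"need at least 3 timepoints, got {t}")
    if region_names is None:
        region_names = tuple(f"ROI{k + 1:03d}" for k in range(n))
    if np.isnan(series).any():
        raise ValueError("series contains NaN")
    sd = series.std(axis=0)
    if np.any(sd == 0):
        bad = [region_names[k] for k in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant time series for region(s): {bad}")
    W = np.corrcoef(series, rowvar=False)
    W = (W + W.T) / 2.0
    np.clip(W, -1.0, 1.0, out=W)
    np.fill_diagonal(W, 1.0)
    return ConnectivityMatrix(W, tuple(region_names), subject_id)


def _edge_order(W: np.ndarray, absolute: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle edges ranked by descending weight, ties by (i, j) lex."""
    n = W.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = np.abs(W[iu, ju]) if absolute else W[iu, ju]
    order = np.lexsort((ju, iu, -vals))
    return iu[order], ju[order]


def binarize_at_sparsity(
    W: ConnectivityMatrix, s: float, absolute: bool = False
) -> np.ndarray:
    """Binary adjacency keeping the ``round(s * n(n-1)/2)`` strongest edges.

    Ranking is by signed correlation by default (``absolute=True`` ranks by
    magnitude); ties at the cut are broken by ascending (i, j) edge index.
    """
    if not 0.0 < s < 1.0:
        raise ValueError(f"sparsity must lie in (0, 1), got {s}")
    n = W.n_regions
    m = round_half_away(s * n * (n - 1) / 2)
    if m == 0:
        raise ValueError(
            f"sparsity {s} keeps zero edges at n={n}; grid misconfigured"
        )
    ei, ej = _edge_order(W.values, absolute=absolute)
    A = np.zeros((n, n), dtype=np.uint8)
    A[ei[:m], ej[:m]] = 1
    return A | A.T


def threshold_stack(
    W: ConnectivityMatrix, grid: SparsityGrid, absolute: bool = False
) -> BinaryGraphStack:
    """Binarize ``W`` at every grid value; graphs are nested by construction."""
    n = W.n_regions
    n_pairs = n * (n - 1) // 2
    ei, ej = _edge_order(W.values, absolute=absolute)
    graphs = []
    for s in grid.values:
        m = round_half_away(float(s) * n_pairs)
        if m == 0:
            raise ValueError(
                f"sparsity {s} keeps zero edges at n={n}; grid misconfigured"
            )
        A = np.zeros((n, n), dtype=np.uint8)
        A[ei[:m], ej[:m]] = 1
        graphs.append(A | A.T)
    return BinaryGraphStack(grid.values, tuple(graphs), W.subject_id)
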