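"""Graph-theory measurements on binary networks and their sparsity-grid AUCs.

Global measurements: characteristic path length (Lp), clustering
coefficient (Cp), normalized path length (lambda) and clustering (gamma)
against degree-preserving rewired null networks, small-world index
(sigma = gamma/lambda), global and local efficiency, modularity (Q),
assortativity (Ar), hierarchy (Hr) and synchronization (Sr).

Nodal measurements: degree centrality, nodal efficiency, betweenness
centrality, shortest path length and nodal clustering coefficient.

Each measurement is computed at every sparsity threshold of a
:class:`~mkfbn.fbn.BinaryGraphStack` and aggregated into a single
area-under-the-curve (AUC) feature, defined literally as the sum of the
per-threshold values (a step-weighted variant multiplies by the grid step).

Disconnected graphs are expected at low sparsity: path-length averages run
over reachable pairs only, while efficiency-based measures treat
unreachable pairs as zero contribution natively.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import igraph
import numpy as np
import pandas as pd
from numba import njit
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .fbn import BinaryGraphStack, SparsityGrid

__all__ = [
    "NullModelConfig",
    "NodalMetrics",
    "GlobalMetrics",
    "GLOBAL_METRIC_ORDER",
    "NODAL_METRIC_ORDER",
    "nodal_metrics",
    "global_metrics",
    "rewire_null",
    "auc_over_thresholds",
    "stack_metric_curves",
    "subject_metric_aucs",
]

logger = logging.getLogger(__name__)

#: column order of the global feature block (fixed report order)
GLOBAL_METRIC_ORDER = (
    "Lp", "Cp", "lambda", "gamma", "sigma",
    "Eglobal", "Elocal", "Q", "Ar", "Hr", "Sr",
)

#: metric-major order of the nodal feature block
NODAL_METRIC_ORDER = (
    "degree", "efficiency", "betweenness", "shortest_path", "clustering",
)


@dataclass(frozen=True)
class NullModelConfig:
    """Degree-preserving rewired null ensemble for gamma/lambda."""

    n_nulls: int = 100
    swaps_per_edge: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nulls < 1:
            raise ValueError(f"n_nulls must be >= 1, got {self.n_nulls}")
        if self.swaps_per_edge < 1:
            raise ValueError("swaps_per_edge must be >= 1")


@dataclass(frozen=True)
class NodalMetrics:
    degree: np.ndarray
    efficiency: np.ndarray
    betweenness: np.ndarray
    shortest_path: np.ndarray
    clustering: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in NODAL_METRIC_ORDER}


@dataclass(frozen=True)
class GlobalMetrics:
    Lp: float
    Cp: float
    lam: float
    gamma: float
    sigma: float
    Eglobal: float
    Elocal: float
    Q: float
    Ar: float
    Hr: float
    Sr: float
    flags: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        d = {name: getattr(self, name) for name in GLOBAL_METRIC_ORDER if name != "lambda"}
        d["lambda"] = self.lam
        return {name: d[name] for name in GLOBAL_METRIC_ORDER}


def _check_adjacency(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {A.shape}")
    if not np.isin(A, (0, 1)).all():
        raise ValueError("adjacency must be binary (entries in {0, 1})")
    if (A != A.T).any():
        raise ValueError("adjacency must be symmetric")
    if np.diag(A).any():
        raise ValueError("adjacency must have a zero diagonal")
    return A.astype(np.uint8)


def _igraph_from_adjacency(A: np.ndarray) -> igraph.Graph:
    iu, ju = np.nonzero(np.triu(A, k=1))
    return igraph.Graph(n=A.shape[0], edges=list(zip(iu.tolist(), ju.tolist())))


def _distances(A: np.ndarray) -> np.ndarray:
    return shortest_path(csr_matrix(A.astype(float)), method="D", unweighted=True,
                         directed=False)


def _nodal_clustering(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    Af = A.astype(float)
    k = Af.sum(axis=1)
    triangles = np.diag(Af @ Af @ Af) / 2.0
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        C = np.where(denom > 0, 2.0 * triangles / denom, 0.0)
    return C, k


def nodal_metrics(A: np.ndarray) -> NodalMetrics:
    """The five per-region measurements on one binary graph.

    Shortest path length is the mean distance to reachable nodes (0 for an
    isolated node); betweenness uses unordered pairs with endpoints
    excluded.
    """
    A = _check_adjacency(A)
    n = A.shape[0]
    C, k = _nodal_clustering(A)
    D = _distances(A)
    finite = np.isfinite(D) & ~np.eye(n, dtype=bool)
    n_reach = finite.sum(axis=1)
    Dz = np.where(finite, D, 0.0)
    with np.errstate(invalid="ignore"):
        spl = np.where(n_reach > 0, Dz.sum(axis=1) / np.maximum(n_reach, 1), 0.0)
    with np.errstate(divide="ignore"):
        inv = np.where(finite, 1.0 / np.where(finite, D, 1.0), 0.0)
    eff = inv.sum(axis=1) / (n - 1)
    btw = np.asarray(_igraph_from_adjacency(A).betweenness(), dtype=float)
    return NodalMetrics(k, eff, btw, spl, C)


def _cp_lp(A: np.ndarray) -> tuple[float, float]:
    """Mean clustering and characteristic path length (reachable pairs only)."""
    C, _ = _nodal_clustering(A)
    D = _distances(A)
    n = A.shape[0]
    iu = np.triu_indices(n, k=1)
    d = D[iu]
    d = d[np.isfinite(d)]
    Lp = float(d.mean()) if d.size else float("nan")
    return float(C.mean()), Lp


def _global_efficiency(A: np.ndarray) -> float:
    n = A.shape[0]
    if n < 2:
        return 0.0
    D = _distances(A)
    iu = np.triu_indices(n, k=1)
    with np.errstate(divide="ignore"):
        inv = 1.0 / D[iu]
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.mean())


def global_metrics(
    A: np.ndarray,
    nulls: NullModelConfig | None = None,
    null_graphs: list[np.ndarray] | None = None,
) -> GlobalMetrics:
    """The eleven global measurements on one binary graph.

    gamma and lambda normalize Cp and Lp by their means over a
    degree-preserving rewired ensemble (pass ``nulls`` to generate it, or
    ``null_graphs`` to reuse one).  When both the graph and its nulls have
    zero clustering the ratio is taken as 1 (the ensemble degenerates to
    the graph itself).  Undefined values (assortativity of a regular graph,
    hierarchy with < 2 eligible nodes) are returned as NaN and named in
    ``flags``.
    """
    A = _check_adjacency(A)
    n = A.shape[0]
    if A.sum() == 0:
        raise ValueError("graph has no edges")
    flags: list[str] = []

    Cp, Lp = _cp_lp(A)
    Eglob = _global_efficiency(A)

    # local efficiency: global efficiency of each open neighborhood
    eloc = np.zeros(n)
    for v in range(n):
        nb = np.flatnonzero(A[v])
        if nb.size >= 2:
            eloc[v] = _global_efficiency(A[np.ix_(nb, nb)])
    Elocal = float(eloc.mean())

    # normalization against the rewired ensemble
    if null_graphs is None:
        cfg = nulls if nulls is not None else NullModelConfig()
        null_graphs = rewire_null(A, cfg)
    null_cp = np.array([_cp_lp(g)[0] for g in null_graphs])
    null_lp = np.array([_cp_lp(g)[1] for g in null_graphs])
    mean_cp = float(null_cp.mean())
    mean_lp = float(np.nanmean(null_lp))
    if mean_cp > 0:
        gamma = Cp / mean_cp
    elif Cp == 0:
        gamma = 1.0
    else:
        gamma = float("nan")
        flags.append("gamma")
    lam = Lp / mean_lp if mean_lp > 0 else float("nan")
    sigma = gamma / lam if np.isfinite(gamma) and np.isfinite(lam) and lam != 0 else float("nan")

    # modularity of the greedy agglomerative (CNM) partition
    g = _igraph_from_adjacency(A)
    membership = g.community_fastgreedy().as_clustering().membership
    Q = float(g.modularity(membership))

    # assortativity: Pearson correlation of endpoint degrees over edges
    k = A.sum(axis=1).astype(float)
    iu, ju = np.nonzero(np.triu(A, k=1))
    x = np.concatenate([k[iu], k[ju]])
    y = np.concatenate([k[ju], k[iu]])
    if x.std() == 0 or y.std() == 0:
        Ar = float("nan")
        flags.append("Ar")
    else:
        Ar = float(np.corrcoef(x, y)[0, 1])

    # hierarchy: negated slope of log C_i on log k_i (k_i >= 2, C_i > 0)
    C, _ = _nodal_clustering(A)
    elig = (k >= 2) & (C > 0)
    if elig.sum() < 2 or np.unique(k[elig]).size < 2:
        Hr = float("nan")
        flags.append("Hr")
    else:
        slope = np.polyfit(np.log(k[elig]), np.log(C[elig]), 1)[0]
        Hr = float(-slope)

    # synchronization: Laplacian eigenratio lambda_2 / lambda_max
    L = np.diag(k) - A.astype(float)
    ev = np.linalg.eigvalsh(L)
    Sr = float(ev[1] / ev[-1]) if ev[-1] > 0 else float("nan")

    return GlobalMetrics(Lp, Cp, lam, gamma, sigma, Eglob, Elocal, Q, Ar, Hr, Sr,
                         tuple(flags))


@njit(cache=False)
def _swap_edges(adj, edges, attempts, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    n_edges = edges.shape[0]
    swapped = 0
    for _ in range(attempts):
        e1 = np.random.randint(n_edges)
        e2 = np.random.randint(n_edges)
        if e1 == e2:
            continue
        a, b = edges[e1, 0], edges[e1, 1]
        c, d = edges[e2, 0], edges[e2, 1]
        if np.random.randint(2) == 1:
            c, d = d, c
        # propose (a, d) and (c, b)
        if a == d or c == b:
            continue
        if adj[a, d] == 1 or adj[c, b] == 1:
            continue
        adj[a, b] = 0; adj[b, a] = 0
        adj[c, d] = 0; adj[d, c] = 0
        adj[a, d] = 1; adj[d, a] = 1
        adj[c, b] = 1; adj[b, c] = 1
        edges[e1, 0], edges[e1, 1] = a, d
        edges[e2, 0], edges[e2, 1] = c, b
        swapped += 1
    return swapped


def rewire_null(A: np.ndarray, cfg: NullModelConfig) -> list[np.ndarray]:
    """Degree-preserving random rewirings of ``A`` via double-edge swaps.

    Each null attempts ``swaps_per_edge * |E|`` swaps.  Graphs admitting no
    valid swap (e.g. a star or a lone triangle) come back identical to the
    input.  Deterministic given ``cfg.seed``.
    """
    A = _check_adjacency(A)
    iu, ju = np.nonzero(np.triu(A, k=1))
    if iu.size == 0:
        raise ValueError("graph has no edges")
    nulls = []
    attempts = int(cfg.swaps_per_edge) * iu.size
    any_swapped = False
    for r in range(cfg.n_nulls):
        adj = A.copy()
        edges = np.stack([iu, ju], axis=1).astype(np.int64)
        seed = (int(cfg.seed) * 1000003 + r) % (2**31)
        n_sw = _swap_edges(adj, edges, attempts, seed)
        any_swapped = any_swapped or n_sw > 0
        nulls.append(adj)
    if not any_swapped:
        logger.debug("no valid double-edge swap found; nulls equal the input graph")
    return nulls


def auc_over_thresholds(
    values: np.ndarray, grid: SparsityGrid, mode: str = "sum"
) -> float:
    """Aggregate one per-threshold metric curve into a scalar.

    ``sum`` is the literal definition (sum of the per-threshold values);
    ``step`` multiplies the sum by the grid step.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (len(grid),):
        raise ValueError(
            f"expected {len(grid)} values (one per grid point), got {values.shape}"
        )
    if np.isnan(values).any():
        raise ValueError(
            f"missing values at grid positions {np.flatnonzero(np.isnan(values)).tolist()}"
        )
    total = float(values.sum())
    if mode == "sum":
        return total
    if mode == "step":
        return float(grid.step) * total
    raise ValueError(f"unknown AUC mode {mode!r} (expected 'sum' or 'step')")


def stack_metric_curves(
    stack: BinaryGraphStack, nulls: NullModelConfig | None = None
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """All measurements at every threshold of one subject's stack.

    Returns a (threshold x global-metric) frame and a dict of
    (threshold x region) arrays for the nodal metrics.
    """
    cfg = nulls if nulls is not None else NullModelConfig()
    glob_rows = []
    nodal = {name: [] for name in NODAL_METRIC_ORDER}
    for A in stack.graphs:
        gm = global_metrics(A, nulls=cfg)
        glob_rows.append(gm.as_dict())
        nm = nodal_metrics(A)
        for name, vec in nm.as_dict().items():
            nodal[name].append(vec)
    global_df = pd.DataFrame(glob_rows, index=np.asarray(stack.thresholds))
    global_df.index.name = "threshold"
    return global_df, {name: np.stack(v) for name, v in nodal.items()}


def subject_metric_aucs(
    stack: BinaryGraphStack,
    grid: SparsityGrid,
    nulls: NullModelConfig | None = None,
    mode: str = "sum",
) -> tuple[dict[str, float], dict[str, np.ndarray]]:
    """Per-metric AUC features for one subject.

    Thresholds where a global metric is undefined (flagged NaN, e.g.
    assortativity of a perfectly regular graph) are imputed as 0 before
    aggregation, with a warning; nodal metrics are always defined.
    """
    global_df, nodal_curves = stack_metric_curves(stack, nulls)
    n_missing = int(global_df.isna().to_numpy().sum())
    if n_missing:
        warnings.warn(
            f"{n_missing} undefined global metric value(s) imputed as 0 "
            f"for subject {stack.subject_id!r}",
            RuntimeWarning,
            stacklevel=2,
        )
        global_df = global_df.fillna(0.0)
    global_aucs = {
        name: auc_over_thresholds(global_df[name].to_numpy(), grid, mode)
        for name in GLOBAL_METRIC_ORDER
    }
    nodal_aucs = {}
    for name, curves in nodal_curves.items():
        scale = float(grid.step) if mode == "step" else 1.0
        nodal_aucs[name] = curves.sum(axis=0) * scale
    return global_aucs, nodal_aucs
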