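"""Feature assembly, fold-wise t-test selection, and consensus connections.

Each subject contributes three feature blocks: the upper-triangle
connection weights of the Pearson network, the 11 global graph-metric
AUCs, and the 5-per-region nodal graph-metric AUCs.  Within every
cross-validation fold the features are filtered by a two-sample t-test
(p < alpha) computed on the training subjects only; connections selected
across the whole validation loop form the consensus set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fbn import ConnectivityMatrix
from .metrics import GLOBAL_METRIC_ORDER, NODAL_METRIC_ORDER

__all__ = [
    "BLOCK_NAMES",
    "FeatureBlocks",
    "CohortFeatures",
    "SelectionMask",
    "ConsensusResult",
    "feature_index_maps",
    "extract_features",
    "assemble_cohort_features",
    "ttest_select",
    "consensus_connections",
]

logger = logging.getLogger(__name__)

BLOCK_NAMES = ("connection", "global", "nodal")


def feature_index_maps(region_names: Sequence[str]) -> dict[str, list]:
    """Bijective maps from feature position to meaning, per block."""
    n = len(region_names)
    iu, ju = np.triu_indices(n, k=1)
    return {
        "connection": [(int(i), int(j)) for i, j in zip(iu, ju)],
        "global": list(GLOBAL_METRIC_ORDER),
        "nodal": [(m, r) for m in NODAL_METRIC_ORDER for r in range(n)],
    }


@dataclass(frozen=True)
class FeatureBlocks:
    """One subject's three feature vectors."""

    connection: np.ndarray
    global_: np.ndarray
    nodal: np.ndarray
    subject_id: str = ""

    def block(self, name: str) -> np.ndarray:
        return {"connection": self.connection, "global": self.global_,
                "nodal": self.nodal}[name]


def extract_features(
    W: ConnectivityMatrix,
    global_aucs: Mapping[str, float],
    nodal_aucs: Mapping[str, np.ndarray],
) -> FeatureBlocks:
    """Assemble a subject's blocks in the canonical deterministic order.

    Connections follow lexicographic (i, j); global metrics follow the
    fixed report order; nodal features are metric-major then region index.
    """
    n = W.n_regions
    iu, ju = np.triu_indices(n, k=1)
    conn = W.values[iu, ju]
    missing = [m for m in GLOBAL_METRIC_ORDER if m not in global_aucs]
    missing += [m for m in NODAL_METRIC_ORDER if m not in nodal_aucs]
    if missing:
        raise KeyError(f"missing metric values for: {missing}")
    glob = np.array([float(global_aucs[m]) for m in GLOBAL_METRIC_ORDER])
    nodal_parts = []
    for m in NODAL_METRIC_ORDER:
        v = np.asarray(nodal_aucs[m], dtype=float)
        if v.shape != (n,):
            raise ValueError(f"nodal metric {m!r} has shape {v.shape}, expected ({n},)")
        nodal_parts.append(v)
    return FeatureBlocks(conn, glob, np.concatenate(nodal_parts), W.subject_id)


@dataclass(frozen=True)
class CohortFeatures:
    """Stacked feature blocks for a whole cohort (subjects in rows)."""

    blocks: dict[str, np.ndarray]
    labels: np.ndarray
    subject_ids: tuple[str, ...]
    region_names: tuple[str, ...]
    index_maps: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_sub = len(self.subject_ids)
        for name, X in self.blocks.items():
            if X.shape[0] != n_sub:
                raise ValueError(f"block {name!r} has {X.shape[0]} rows, "
                                 f"expected {n_sub}")
        if len(self.labels) != n_sub:
            raise ValueError("labels length does not match subjects")

    def __len__(self) -> int:
        return len(self.subject_ids)


def assemble_cohort_features(
    per_subject: Sequence[FeatureBlocks],
    labels: Sequence[int],
    region_names: Sequence[str],
) -> CohortFeatures:
    blocks = {
        "connection": np.stack([f.connection for f in per_subject]),
        "global": np.stack([f.global_ for f in per_subject]),
        "nodal": np.stack([f.nodal for f in per_subject]),
    }
    return CohortFeatures(
        blocks,
        np.asarray(labels, dtype=int),
        tuple(f.subject_id for f in per_subject),
        tuple(region_names),
        feature_index_maps(region_names),
    )


@dataclass(frozen=True)
class SelectionMask:
    """Per-block boolean selection with the p-values behind it."""

    masks: dict[str, np.ndarray]
    pvalues: dict[str, np.ndarray]
    alpha: float
    fold_id: int = -1
    flagged: tuple[str, ...] = ()  # blocks where the fallback kicked in


def ttest_select(
    blocks: Mapping[str, np.ndarray],
    labels: np.ndarray,
    alpha: float = 0.05,
    welch: bool = False,
    fold_id: int = -1,
) -> SelectionMask:
    """Two-sample two-tailed t-test per feature; keep p < alpha.

    Pooled-variance (Student) by default, Welch with ``welch=True``.
    Features with zero variance in both groups get p = NaN and are never
    selected.  A block where nothing survives keeps all of its features
    (the filter found no evidence, so it does not filter) and is flagged,
    keeping downstream kernels defined without a winner's-curse pick.
    """
    labels = np.asarray(labels)
    pos = labels == 1
    neg = labels == -1
    if not pos.any() or not neg.any():
        raise ValueError("both classes must be present in the training labels")
    masks: dict[str, np.ndarray] = {}
    pvals: dict[str, np.ndarray] = {}
    flagged = []
    for name, X in blocks.items():
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(X[pos], X[neg], axis=0, equal_var=not welch)
        p = np.asarray(res.pvalue, dtype=float)
        mask = np.where(np.isnan(p), False, p < alpha)
        if not mask.any():
            mask = ~np.isnan(p)
            if not mask.any():
                mask = np.ones_like(mask)
            flagged.append(name)
            logger.debug("fold %d: no feature of block %r below alpha; "
                         "kept the whole block unselected", fold_id, name)
        masks[name] = mask
        pvals[name] = p
    return SelectionMask(masks, pvals, float(alpha), fold_id, tuple(flagged))


@dataclass(frozen=True)
class ConsensusResult:
    """Connections selected across the validation loop.

    ``table`` covers the union of selected connections (one row per edge,
    with selection frequency); ``intersection`` is the subset present in
    every fold; ``most_significant`` is the edge whose worst-case (max over
    folds) p-value is smallest.
    """

    table: pd.DataFrame
    intersection: pd.DataFrame
    most_significant: tuple[int, int] | None


def consensus_connections(
    fold_masks: Sequence[SelectionMask],
    features: CohortFeatures,
) -> ConsensusResult:
    """Rank connection features by how consistently the folds selected them.

    Each edge is annotated with the sign of the positive-minus-negative
    group mean difference of its connection weight ("increased" /
    "decreased" in the positive class).
    """
    if len(fold_masks) < 2:
        raise ValueError("need at least 2 folds for a consensus analysis")
    sel = np.stack([m.masks["connection"] for m in fold_masks])
    pv = np.stack([m.pvalues["connection"] for m in fold_masks])
    n_folds = sel.shape[0]
    counts = sel.sum(axis=0)
    union = np.flatnonzero(counts > 0)

    X = features.blocks["connection"]
    labels = features.labels
    diff = X[labels == 1].mean(axis=0) - X[labels == -1].mean(axis=0)
    max_p = np.nanmax(pv, axis=0)
    pairs = features.index_maps["connection"]
    names = features.region_names

    rows = []
    for f in union:
        i, j = pairs[f]
        rows.append({
            "i": i, "j": j,
            "region_i": names[i], "region_j": names[j],
            "n_selected": int(counts[f]),
            "frequency": counts[f] / n_folds,
            "direction": "increased" if diff[f] > 0 else "decreased",
            "mean_difference": diff[f],
            "max_p": max_p[f],
        })
    table = pd.DataFrame(
        rows,
        columns=["i", "j", "region_i", "region_j", "n_selected", "frequency",
                 "direction", "mean_difference", "max_p"],
    )
    if len(table):
        table = table.sort_values(
            ["frequency", "max_p", "i", "j"], ascending=[False, True, True, True]
        ).reset_index(drop=True)
    intersection = table[table["n_selected"] == n_folds].reset_index(drop=True)
    if intersection.empty:
        logger.warning("consensus intersection is empty; union has %d edges",
                       len(table))
    most = None
    if len(table):
        best = table.loc[table["max_p"].idxmin()]
        most = (int(best["i"]), int(best["j"]))
    return ConsensusResult(table, intersection, most)
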