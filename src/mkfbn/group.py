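"""Group-level descriptive analyses: mean networks, hubs, metric contrasts.

The group-level network is the element-wise mean of the member subjects'
Pearson networks.  Hubs are the top fraction of regions by a group-level
centrality score (weighted degree of the mean network, or the mean nodal
betweenness AUC).  Between-group contrasts report per-metric (or
per-region) means, standard deviations and two-sample t-tests, flagged at
an uncorrected p < 0.05 with a Benjamini-Hochberg column alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .fbn import ConnectivityMatrix, round_half_away

__all__ = [
    "GroupNetwork",
    "HubTable",
    "group_mean_network",
    "weighted_degree",
    "hub_nodes",
    "compare_group_metrics",
]


@dataclass(frozen=True)
class GroupNetwork:
    label: int
    values: np.ndarray
    region_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if np.abs(self.values - self.values.T).max() > 1e-12:
            raise ValueError("group network must be symmetric")


@dataclass(frozen=True)
class HubTable:
    measure: str
    proportion: float
    table: pd.DataFrame  # columns: region, score, rank


def group_mean_network(
    matrices: Sequence[ConnectivityMatrix], labels: Sequence[int]
) -> dict[int, GroupNetwork]:
    """Element-wise mean connectivity per group (+1 and -1)."""
    labels = np.asarray(labels)
    if len(matrices) != len(labels):
        raise ValueError("one label per matrix required")
    out = {}
    names = matrices[0].region_names
    for g in (+1, -1):
        idx = np.flatnonzero(labels == g)
        if idx.size == 0:
            raise ValueError(f"group {g:+d} is empty")
        M = np.mean([matrices[k].values for k in idx], axis=0)
        M = (M + M.T) / 2.0
        np.fill_diagonal(M, 1.0)
        out[g] = GroupNetwork(g, M, names)
    return out


def weighted_degree(network: GroupNetwork) -> np.ndarray:
    """Sum of off-diagonal connection weights per region."""
    return network.values.sum(axis=1) - np.diag(network.values)


def hub_nodes(
    scores: np.ndarray | GroupNetwork,
    region_names: Sequence[str] | None = None,
    proportion: float = 0.05,
    measure: str = "degree",
) -> HubTable:
    """Top ``round(proportion * n)`` regions by score, ties by region index.

    Pass a :class:`GroupNetwork` to rank by weighted degree of the mean
    network, or any per-region score vector (e.g. mean betweenness AUCs).
    """
    if not 0.0 < proportion < 1.0:
        raise ValueError(f"proportion must lie in (0, 1), got {proportion}")
    if isinstance(scores, GroupNetwork):
        region_names = scores.region_names
        scores = weighted_degree(scores)
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if region_names is None:
        region_names = [f"ROI{k + 1:03d}" for k in range(n)]
    k = round_half_away(proportion * n)
    if k == 0:
        raise ValueError(
            f"proportion {proportion} selects zero of {n} regions"
        )
    order = np.lexsort((np.arange(n), -scores))[:k]
    table = pd.DataFrame({
        "region": [region_names[i] for i in order],
        "score": scores[order],
        "rank": np.arange(1, k + 1),
    })
    return HubTable(measure, float(proportion), table)


def compare_group_metrics(
    values: pd.DataFrame | Mapping[str, np.ndarray],
    labels: Sequence[int],
    alpha: float = 0.05,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-column group contrast: mean +/- sd per group, t, p, significance.

    ``values`` has one row per subject and one column per metric (or per
    region-metric).  Output is sorted by ascending p; zero pooled variance
    yields a NaN p.  ``p_fdr`` adds Benjamini-Hochberg adjusted values.
    """
    df = pd.DataFrame(values)
    labels = np.asarray(labels)
    pos = labels == 1
    neg = labels == -1
    if not pos.any() or not neg.any():
        raise ValueError("both groups must be non-empty")
    X = df.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(X[pos], X[neg], axis=0, equal_var=not welch)
    p = np.asarray(res.pvalue, dtype=float)
    finite = np.isfinite(p)
    p_fdr = np.full_like(p, np.nan)
    if finite.any():
        p_fdr[finite] = multipletests(p[finite], method="fdr_bh")[1]
    out = pd.DataFrame({
        "name": df.columns,
        "mean_pos": X[pos].mean(axis=0),
        "sd_pos": X[pos].std(axis=0, ddof=1),
        "mean_neg": X[neg].mean(axis=0),
        "sd_neg": X[neg].std(axis=0, ddof=1),
        "t": np.asarray(res.statistic, dtype=float),
        "p": p,
        "significant": np.where(np.isnan(p), False, p < alpha),
        "p_fdr": p_fdr,
    })
    return out.sort_values("p", na_position="last", kind="mergesort").reset_index(drop=True)
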