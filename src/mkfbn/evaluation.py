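"""Leave-one-out evaluation of the method configurations, ROC, and DeLong.

Seven configurations are compared: each single feature block (connection
C, global G, nodal N) and every combination (C+G, C+N, G+N, C+G+N).  For
every held-out subject the entire training computation — t-test feature
selection, standardization, kernel construction and (C, beta) tuning —
uses the remaining subjects only.  Performance is summarized as accuracy,
sensitivity and specificity on the pooled fold predictions, plus the ROC
area over the continuous decision values; correlated ROC areas of two
configurations are compared with DeLong's test.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .features import BLOCK_NAMES, CohortFeatures, SelectionMask, ttest_select
from .mksvm import HyperGrid, build_kernel, combine_kernels, decision_values, fit, tune

__all__ = [
    "MethodConfig",
    "METHOD_CONFIGS",
    "FoldRecord",
    "LoocvResult",
    "ConfusionCounts",
    "ROCResult",
    "DelongResult",
    "loocv_run",
    "confusion_metrics",
    "roc_auc",
    "delong_test",
]

logger = logging.getLogger(__name__)

_LETTER = {"C": "connection", "G": "global", "N": "nodal"}


@dataclass(frozen=True)
class MethodConfig:
    """A subset of feature blocks, e.g. identifier 'C+G+N'."""

    identifier: str

    def __post_init__(self) -> None:
        letters = self.identifier.replace(" ", "").split("+")
        if not letters or any(l not in _LETTER for l in letters):
            raise ValueError(f"bad method identifier {self.identifier!r}")
        if len(set(letters)) != len(letters):
            raise ValueError(f"repeated block in {self.identifier!r}")

    @property
    def blocks(self) -> tuple[str, ...]:
        return tuple(_LETTER[l] for l in self.identifier.replace(" ", "").split("+"))


METHOD_CONFIGS = tuple(
    MethodConfig(ident) for ident in ("C", "G", "N", "C+G", "C+N", "G+N", "C+G+N")
)


@dataclass(frozen=True)
class FoldRecord:
    subject_id: str
    true_label: int
    predicted_label: int
    decision_value: float
    C: float
    beta: tuple[float, ...]
    n_selected: dict[str, int]


@dataclass(frozen=True)
class LoocvResult:
    method: MethodConfig
    records: tuple[FoldRecord, ...]
    masks: tuple[SelectionMask, ...]

    @property
    def true_labels(self) -> np.ndarray:
        return np.array([r.true_label for r in self.records])

    @property
    def predicted_labels(self) -> np.ndarray:
        return np.array([r.predicted_label for r in self.records])

    @property
    def decision_values(self) -> np.ndarray:
        return np.array([r.decision_value for r in self.records])


def loocv_run(
    features: CohortFeatures,
    method: MethodConfig,
    hyper: HyperGrid | None = None,
    alpha: float = 0.05,
    welch: bool = False,
    inner_folds: int = 5,
    inner_repeats: int = 1,
    seed: int = 0,
) -> LoocvResult:
    """Leave-one-out cross-validation of one method configuration.

    No information from the held-out subject enters feature selection,
    standardization, kernel normalization or hyperparameter tuning.
    """
    n = len(features)
    if n < 4:
        raise ValueError("need at least 4 subjects for LOOCV")
    labels = features.labels
    if (labels == 1).sum() == 0 or (labels == -1).sum() == 0:
        raise ValueError("both classes must be present")
    hyper = hyper if hyper is not None else HyperGrid()
    used = method.blocks
    t0 = time.perf_counter()
    records = []
    masks = []
    for i in range(n):
        tr = np.arange(n) != i
        y_tr = labels[tr]
        if (y_tr == 1).sum() == 0 or (y_tr == -1).sum() == 0:
            raise ValueError(f"fold {i}: training set contains a single class")
        train_blocks = {b: features.blocks[b][tr] for b in used}
        mask = ttest_select(train_blocks, y_tr, alpha=alpha, welch=welch, fold_id=i)
        kernels = [
            build_kernel(
                train_blocks[b][:, mask.masks[b]],
                features.blocks[b][i][mask.masks[b]],
                block_name=b,
            )
            for b in used
        ]
        grams = [k.gram for k in kernels]
        C, beta, _ = tune(grams, y_tr, hyper, inner_folds=inner_folds,
                          seed=seed, repeats=inner_repeats)
        model = fit(combine_kernels(grams, beta), y_tr, C, beta=beta)
        rows = combine_kernels([k.test_rows for k in kernels], beta)
        f = float(decision_values(model, rows)[0])
        records.append(FoldRecord(
            subject_id=features.subject_ids[i],
            true_label=int(labels[i]),
            predicted_label=1 if f > 0 else -1,
            decision_value=f,
            C=C,
            beta=tuple(float(b) for b in beta),
            n_selected={b: int(mask.masks[b].sum()) for b in used},
        ))
        masks.append(mask)
    logger.info("LOOCV %s: %d folds in %.1f s", method.identifier, n,
                time.perf_counter() - t0)
    return LoocvResult(method, tuple(records), tuple(masks))


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int


def confusion_metrics(result: LoocvResult | tuple) -> dict[str, float]:
    """Accuracy, sensitivity and specificity of pooled fold predictions.

    The positive class is the case-like (+1) group.  A zero denominator
    yields NaN rather than an exception.
    """
    if isinstance(result, LoocvResult):
        true, pred = result.true_labels, result.predicted_labels
    else:
        true, pred = (np.asarray(a) for a in result)
    tp = int(((true == 1) & (pred == 1)).sum())
    fn = int(((true == 1) & (pred == -1)).sum())
    tn = int(((true == -1) & (pred == -1)).sum())
    fp = int(((true == -1) & (pred == 1)).sum())
    total = tp + fp + tn + fn
    return {
        "accuracy": (tp + tn) / total if total else float("nan"),
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "counts": ConfusionCounts(tp, fp, tn, fn),
    }


@dataclass(frozen=True)
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """ROC curve over the continuous decision values (positive class +1)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if (labels == 1).sum() == 0 or (labels == -1).sum() == 0:
        raise ValueError("both classes required for a ROC curve")
    if np.ptp(scores) == 0:
        logger.warning("constant decision values: AUC is 0.5 by convention")
    fpr, tpr, thr = roc_curve(labels, scores, pos_label=1)
    auc = float(roc_auc_score(labels, scores))
    return ROCResult(fpr, tpr, thr, auc)


@dataclass(frozen=True)
class DelongResult:
    auc_a: float
    auc_b: float
    difference: float
    statistic: float
    pvalue: float


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def delong_test(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> DelongResult:
    """DeLong's test for two correlated ROC areas on the same subjects.

    Uses the midrank formulation of the structural components; the
    statistic is the AUC difference over its estimated standard error,
    with a two-sided normal p-value.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    if not (len(scores_a) == len(scores_b) == len(labels)):
        raise ValueError("score vectors must cover the same subjects")
    pos = labels == 1
    neg = labels == -1
    m, n = int(pos.sum()), int(neg.sum())
    if m == 0 or n == 0:
        raise ValueError("both classes required")

    aucs = np.empty(2)
    v10 = np.empty((2, m))
    v01 = np.empty((2, n))
    for idx, s in enumerate((scores_a, scores_b)):
        x, yv = s[pos], s[neg]
        tz = _midrank(np.concatenate([x, yv]))
        tx = _midrank(x)
        ty = _midrank(yv)
        aucs[idx] = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        v10[idx] = (tz[:m] - tx) / n
        v01[idx] = 1.0 - (tz[m:] - ty) / m
    diff = float(aucs[0] - aucs[1])
    s10 = np.cov(v10)
    s01 = np.cov(v01)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0 or diff == 0.0:
        z = 0.0
        p = 1.0 if diff == 0.0 else 0.0
    else:
        z = diff / float(np.sqrt(var))
        p = float(2.0 * stats.norm.sf(abs(z)))
    return DelongResult(float(aucs[0]), float(aucs[1]), diff, z, p)
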