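"""Cohort readers, declarative pipeline configuration, and the full run.

The pipeline realizes the whole analysis end to end: read (or simulate) a
cohort of ROI time series, estimate Pearson networks, binarize over the
sparsity grid, compute graph-metric AUC features, run leave-one-out
classification for every requested method configuration, and write the
group-level descriptive tables.  A single structured YAML config drives
everything; unknown keys are rejected before any computation, and every
output table carries the hash of the generating configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .evaluation import (
    METHOD_CONFIGS,
    LoocvResult,
    MethodConfig,
    confusion_metrics,
    delong_test,
    loocv_run,
    roc_auc,
)
from .fbn import ConnectivityMatrix, SparsityGrid, pearson_fbn, threshold_stack
from .features import (
    CohortFeatures,
    assemble_cohort_features,
    consensus_connections,
    extract_features,
)
from .group import compare_group_metrics, group_mean_network, hub_nodes
from .metrics import (
    NODAL_METRIC_ORDER,
    NullModelConfig,
    subject_metric_aucs,
)
from .mksvm import HyperGrid
from .synthetic import Subject, TimeSeriesCohort

__all__ = [
    "PipelineConfig",
    "read_cohort",
    "estimate_networks",
    "compute_cohort_features",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridSection(_StrictModel):
    start: float = 0.02
    stop: float = 0.50
    step: float = 0.01

    def build(self) -> SparsityGrid:
        return SparsityGrid(self.start, self.stop, self.step)


class NullSection(_StrictModel):
    n_nulls: int = 100
    swaps_per_edge: int = 10

    def build(self, seed: int) -> NullModelConfig:
        return NullModelConfig(self.n_nulls, self.swaps_per_edge, seed)


class HyperSection(_StrictModel):
    c_min_exp: int = -5
    c_max_exp: int = 5
    beta_step: float = 0.1

    def build(self) -> HyperGrid:
        return HyperGrid(
            tuple(2.0 ** k for k in range(self.c_min_exp, self.c_max_exp + 1)),
            self.beta_step,
        )


class PipelineConfig(_StrictModel):
    """Declarative configuration of a full pipeline run."""

    manifest: str
    output_dir: str
    label_map: dict[str, int] | None = None
    grid: GridSection = Field(default_factory=GridSection)
    nulls: NullSection = Field(default_factory=NullSection)
    hyper: HyperSection = Field(default_factory=HyperSection)
    auc_mode: Literal["sum", "step"] = "sum"
    absolute_ranking: bool = False
    alpha: float = 0.05
    welch: bool = False
    methods: list[str] = Field(
        default_factory=lambda: [m.identifier for m in METHOD_CONFIGS]
    )
    inner_folds: int = 5
    inner_repeats: int = 1
    seed: int = 0
    hub_proportion: float = 0.05
    write_connectivity: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def read_cohort(
    manifest_path: str | Path, label_map: dict[str, int] | None = None
) -> TimeSeriesCohort:
    """Load a cohort from a manifest CSV (subject_id, path, label).

    Per-subject files are TSVs with a region-name header; paths are
    relative to the manifest.  String labels are mapped to +1/-1 via
    ``label_map``.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    manifest = pd.read_csv(manifest_path, dtype={"subject_id": str, "label": str})
    required = {"subject_id", "path", "label"}
    if not required.issubset(manifest.columns):
        raise ValueError(
            f"manifest must have columns {sorted(required)}, "
            f"got {list(manifest.columns)}"
        )
    subjects = []
    region_names: tuple[str, ...] | None = None
    for _, row in manifest.iterrows():
        sid = str(row["subject_id"])
        fpath = manifest_path.parent / str(row["path"])
        if not fpath.exists():
            raise FileNotFoundError(f"subject {sid}: file not found: {fpath}")
        try:
            df = pd.read_csv(fpath, sep="\t", float_precision="round_trip")
        except pd.errors.ParserError as exc:
            raise ValueError(f"subject {sid}: malformed file {fpath}: {exc}") from exc
        numeric = df.apply(pd.to_numeric, errors="coerce")
        if numeric.isna().any().any():
            r, c = np.argwhere(numeric.isna().to_numpy())[0]
            raise ValueError(
                f"subject {sid}: non-numeric cell at data row {r + 1}, "
                f"column {df.columns[c]!r}"
            )
        names = tuple(df.columns)
        if region_names is None:
            region_names = names
        elif names != region_names:
            raise ValueError(f"subject {sid}: region names differ from first subject")
        raw_label = str(row["label"])
        if label_map and raw_label in label_map:
            label = int(label_map[raw_label])
        else:
            try:
                label = int(float(raw_label))
            except ValueError as exc:
                raise ValueError(
                    f"subject {sid}: label {raw_label!r} is not +1/-1 and has "
                    f"no label_map entry"
                ) from exc
        if label not in (+1, -1):
            raise ValueError(f"subject {sid}: label must map to +1 or -1, got {label}")
        subjects.append(Subject(sid, label, numeric.to_numpy(dtype=float)))
    if not subjects:
        raise ValueError("manifest lists no subjects")
    return TimeSeriesCohort(tuple(subjects), region_names)


def estimate_networks(cohort: TimeSeriesCohort) -> list[ConnectivityMatrix]:
    return [
        pearson_fbn(s.data, cohort.region_names, s.subject_id)
        for s in cohort.subjects
    ]


def compute_cohort_features(
    cohort: TimeSeriesCohort,
    grid: SparsityGrid,
    nulls: NullModelConfig,
    auc_mode: str = "sum",
    absolute_ranking: bool = False,
    matrices: list[ConnectivityMatrix] | None = None,
) -> tuple[CohortFeatures, list[ConnectivityMatrix]]:
    """Estimate networks, threshold, and aggregate metric AUCs per subject."""
    if matrices is None:
        matrices = estimate_networks(cohort)
    per_subject = []
    t0 = time.perf_counter()
    for W in matrices:
        stack = threshold_stack(W, grid, absolute=absolute_ranking)
        g_aucs, n_aucs = subject_metric_aucs(stack, grid, nulls, auc_mode)
        per_subject.append(extract_features(W, g_aucs, n_aucs))
    logger.info("metric AUCs for %d subjects in %.1f s", len(matrices),
                time.perf_counter() - t0)
    features = assemble_cohort_features(
        per_subject, cohort.labels, cohort.region_names
    )
    return features, matrices


def _hub_prop(prop: float, n_regions: int) -> float:
    """Clamp a hub proportion so it selects at least one region."""
    return max(prop, 1.0 / n_regions)


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str, index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=index)


def _summary_frame(results: dict[str, LoocvResult]) -> pd.DataFrame:
    rows = []
    for ident, res in results.items():
        cm = confusion_metrics(res)
        roc = roc_auc(res.decision_values, res.true_labels)
        rows.append({
            "method": ident,
            "accuracy": cm["accuracy"],
            "sensitivity": cm["sensitivity"],
            "specificity": cm["specificity"],
            "auc": roc.auc,
            "accuracy_pct": f"{100 * cm['accuracy']:.2f}",
            "sensitivity_pct": f"{100 * cm['sensitivity']:.2f}",
            "specificity_pct": f"{100 * cm['specificity']:.2f}",
        })
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and write the results directory.

    Identical config (hence identical hash) and seed produce byte-identical
    tables.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    grid = config.grid.build()
    nulls = config.nulls.build(config.seed)
    hyper = config.hyper.build()

    cohort = read_cohort(config.manifest, config.label_map)
    logger.info("cohort: %d subjects, %d regions, %d timepoints",
                len(cohort), len(cohort.region_names),
                cohort.subjects[0].data.shape[0])

    features, matrices = compute_cohort_features(
        cohort, grid, nulls, config.auc_mode, config.absolute_ranking
    )

    if config.write_connectivity:
        for W in matrices:
            df = pd.DataFrame(W.values, index=W.region_names, columns=W.region_names)
            _write_csv(df, out / "connectivity" / f"{W.subject_id}.csv", chash,
                       index=True)

    # feature tables
    glob_df = pd.DataFrame(features.blocks["global"],
                           index=list(features.subject_ids),
                           columns=features.index_maps["global"])
    _write_csv(glob_df, out / "features" / "global_aucs.csv", chash, index=True)
    nodal_cols = [f"{m}:{features.region_names[r]}"
                  for m, r in features.index_maps["nodal"]]
    nodal_df = pd.DataFrame(features.blocks["nodal"],
                            index=list(features.subject_ids), columns=nodal_cols)
    _write_csv(nodal_df, out / "features" / "nodal_aucs.csv", chash, index=True)
    conn_cols = [f"{features.region_names[i]}--{features.region_names[j]}"
                 for i, j in features.index_maps["connection"]]
    conn_df = pd.DataFrame(features.blocks["connection"],
                           index=list(features.subject_ids), columns=conn_cols)
    _write_csv(conn_df, out / "features" / "connection.csv", chash, index=True)

    # classification
    results: dict[str, LoocvResult] = {}
    for ident in config.methods:
        method = MethodConfig(ident)
        res = loocv_run(features, method, hyper, alpha=config.alpha,
                        welch=config.welch, inner_folds=config.inner_folds,
                        inner_repeats=config.inner_repeats, seed=config.seed)
        results[ident] = res
        folds = pd.DataFrame([{
            "subject_id": r.subject_id,
            "true_label": r.true_label,
            "predicted_label": r.predicted_label,
            "decision_value": r.decision_value,
            "C": r.C,
            "beta": "/".join(f"{b:.2f}" for b in r.beta),
            **{f"n_selected_{k}": v for k, v in r.n_selected.items()},
        } for r in res.records])
        safe = ident.replace("+", "")
        _write_csv(folds, out / "classification" / f"folds_{safe}.csv", chash)
    _write_csv(_summary_frame(results), out / "classification" / "summary.csv", chash)

    # pairwise DeLong comparisons
    idents = list(results)
    rows = []
    for a in idents:
        for b in idents:
            if a >= b:
                continue
            d = delong_test(results[a].decision_values, results[b].decision_values,
                            results[a].true_labels)
            rows.append({"method_a": a, "method_b": b, "auc_a": d.auc_a,
                         "auc_b": d.auc_b, "difference": d.difference,
                         "z": d.statistic, "p": d.pvalue})
    if rows:
        _write_csv(pd.DataFrame(rows), out / "classification" / "delong.csv", chash)

    # consensus connections from the richest method that uses connections
    conn_methods = [i for i in idents if "connection" in MethodConfig(i).blocks]
    if conn_methods:
        pick = max(conn_methods, key=lambda i: len(MethodConfig(i).blocks))
        cons = consensus_connections(results[pick].masks, features)
        _write_csv(cons.table, out / "consensus" / "union.csv", chash)
        _write_csv(cons.intersection, out / "consensus" / "intersection.csv", chash)

    # group-level analysis
    nets = group_mean_network(matrices, features.labels)
    for g, net in nets.items():
        tag = "pos" if g == 1 else "neg"
        df = pd.DataFrame(net.values, index=net.region_names,
                          columns=net.region_names)
        _write_csv(df, out / "group" / f"mean_network_{tag}.csv", chash, index=True)
        for prop in sorted({config.hub_proportion, 0.20}):
            hubs = hub_nodes(net, proportion=_hub_prop(prop, len(net.region_names)))
            _write_csv(hubs.table,
                       out / "group" / f"hubs_degree_{tag}_p{int(prop * 100):02d}.csv",
                       chash)
    _write_csv(
        compare_group_metrics(glob_df, features.labels, alpha=config.alpha,
                              welch=config.welch),
        out / "group" / "global_metric_comparison.csv", chash)
    n_regions = len(features.region_names)
    for metric in ("degree", "betweenness"):
        k = NODAL_METRIC_ORDER.index(metric)
        cols = slice(k * n_regions, (k + 1) * n_regions)
        sub = pd.DataFrame(features.blocks["nodal"][:, cols],
                           columns=list(features.region_names))
        _write_csv(compare_group_metrics(sub, features.labels, alpha=config.alpha,
                                         welch=config.welch),
                   out / "group" / f"{metric}_comparison.csv", chash)
        # betweenness hubs from mean nodal AUCs per group
        if metric == "betweenness":
            for g in (+1, -1):
                tag = "pos" if g == 1 else "neg"
                score = sub[features.labels == g].mean(axis=0).to_numpy()
                for prop in sorted({config.hub_proportion, 0.20}):
                    hubs = hub_nodes(score, features.region_names,
                                     proportion=_hub_prop(prop, n_regions),
                                     measure="betweenness")
                    _write_csv(
                        hubs.table,
                        out / "group" /
                        f"hubs_betweenness_{tag}_p{int(prop * 100):02d}.csv",
                        chash)

    manifest = {
        "config": config.model_dump(),
        "config_hash": chash,
        "seed": config.seed,
        "package_version": __version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
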