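"""Synthetic two-group cohorts of ROI time series with planted connectivity effects.

The generator emulates a case/control resting-state cohort: every subject's
regional time series are drawn from a zero-mean multivariate normal whose
population correlation matrix is shared within a group.  The two group
matrices are identical except on a configurable set of planted edges, where
the positive (case-like) group's correlation is shifted by ``effect_size``.
Additive white Gaussian noise on the series attenuates all correlations
uniformly, mimicking measurement noise.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "Subject",
    "TimeSeriesCohort",
    "build_group_correlation_targets",
    "simulate_cohort",
    "write_cohort",
]

#: smallest admissible eigenvalue of a repaired correlation matrix
_EIG_FLOOR = 1e-6


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated two-group cohort.

    Defaults mirror a 90-region parcellation with 170 retained volumes and
    a 45 (case) / 47 (control) split.
    """

    n_regions: int = 90
    n_timepoints: int = 170
    n_group_pos: int = 45
    n_group_neg: int = 47
    planted_edges: tuple[tuple[int, int], ...] = ()
    effect_size: float = 0.0
    planted_effects: tuple[float, ...] | None = None  # per-edge override
    base_density: float = 0.25
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 3:
            raise ValueError(f"n_regions must be >= 3, got {self.n_regions}")
        if self.n_timepoints < 10:
            raise ValueError(f"n_timepoints must be >= 10, got {self.n_timepoints}")
        if self.n_group_pos < 0 or self.n_group_neg < 0:
            raise ValueError("group sizes must be non-negative")
        if not 0.0 <= self.base_density <= 1.0:
            raise ValueError(f"base_density must be in [0, 1], got {self.base_density}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        edges = []
        seen = set()
        for e in self.planted_edges:
            i, j = int(e[0]), int(e[1])
            if i == j:
                raise ValueError(f"planted edge {e} has identical endpoints")
            if not (0 <= i < self.n_regions and 0 <= j < self.n_regions):
                raise ValueError(f"planted edge {e} outside [0, {self.n_regions})")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"planted edge {key} listed twice")
            seen.add(key)
            edges.append(key)
        object.__setattr__(self, "planted_edges", tuple(edges))
        if self.planted_effects is not None:
            if len(self.planted_effects) != len(edges):
                raise ValueError(
                    "planted_effects must have one entry per planted edge"
                )
            object.__setattr__(
                self, "planted_effects", tuple(float(e) for e in self.planted_effects)
            )

    def edge_effects(self) -> tuple[float, ...]:
        """Per-edge correlation shifts (the scalar effect_size unless
        overridden edge-by-edge)."""
        if self.planted_effects is not None:
            return self.planted_effects
        return tuple(self.effect_size for _ in self.planted_edges)


@dataclass(frozen=True)
class Subject:
    subject_id: str
    label: int  # +1 case-like, -1 control-like
    data: np.ndarray  # timepoints x regions


@dataclass(frozen=True)
class TimeSeriesCohort:
    """Ordered collection of labelled per-subject ROI time-series matrices."""

    subjects: tuple[Subject, ...]
    region_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.subjects:
            return
        shape = self.subjects[0].data.shape
        for s in self.subjects:
            if s.data.shape != shape:
                raise ValueError(
                    f"subject {s.subject_id} has shape {s.data.shape}, expected {shape}"
                )
            if s.label not in (+1, -1):
                raise ValueError(f"subject {s.subject_id} label must be +1 or -1")
            var = s.data.var(axis=0)
            if np.any(var == 0):
                bad = [self.region_names[k] for k in np.flatnonzero(var == 0)]
                raise ValueError(
                    f"subject {s.subject_id} has constant column(s): {bad}"
                )
        if len(self.region_names) != shape[1]:
            raise ValueError("region_names length does not match data columns")

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.subjects], dtype=int)

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    def __len__(self) -> int:
        return len(self.subjects)


def _repair_correlation(R: np.ndarray, floor: float = _EIG_FLOOR) -> np.ndarray:
    """Eigenvalue-floor a symmetric matrix and re-standardize to unit diagonal.

    Iterates because the diagonal re-normalization can push the smallest
    eigenvalue slightly below the floor again.
    """
    R = (R + R.T) / 2.0
    for _ in range(100):
        w, V = np.linalg.eigh(R)
        if w[0] >= floor:
            break
        w = np.maximum(w, 10 * floor)
        R = (V * w) @ V.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    return R


def build_group_correlation_targets(
    spec: CohortSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Population correlation targets ``(R_neg, R_pos)`` for the two groups.

    The shared base structure is a random sparse symmetric matrix: each
    off-diagonal pair is nonzero with probability ``base_density`` with a
    weight drawn uniformly from [0.2, 0.5], followed by positive-definite
    repair.  ``R_pos`` equals the repaired ``R_neg`` shifted by
    ``effect_size`` on the planted edges (then repaired again).
    """
    n = spec.n_regions
    rng = np.random.default_rng([int(spec.seed) % (2**31), 17])
    iu = np.triu_indices(n, k=1)
    weights = np.where(
        rng.random(len(iu[0])) < spec.base_density,
        rng.uniform(0.2, 0.5, size=len(iu[0])),
        0.0,
    )
    R = np.zeros((n, n))
    R[iu] = weights
    R = R + R.T
    np.fill_diagonal(R, 1.0)
    R_neg = _repair_correlation(R)

    R_pos = R_neg.copy()
    for (i, j), eff in zip(spec.planted_edges, spec.edge_effects()):
        target = R_neg[i, j] + eff
        if not -1.0 < target < 1.0:
            raise ValueError(
                f"effect {eff} pushes edge ({i}, {j}) "
                f"correlation to {target:.4f}, outside (-1, 1)"
            )
        R_pos[i, j] = R_pos[j, i] = target
    R_pos = _repair_correlation(R_pos)
    return R_neg, R_pos


def default_region_names(n_regions: int) -> tuple[str, ...]:
    return tuple(f"ROI{k + 1:03d}" for k in range(n_regions))


def simulate_cohort(spec: CohortSpec) -> TimeSeriesCohort:
    """Draw a labelled cohort of multivariate-normal ROI time series.

    Positive-group subjects come first.  Generation is a pure function of
    ``spec`` (including its seed).
    """
    if spec.n_group_pos == 0 or spec.n_group_neg == 0:
        raise ValueError("both groups must contain at least one subject")
    R_neg, R_pos = build_group_correlation_targets(spec)
    L_neg = np.linalg.cholesky(R_neg)
    L_pos = np.linalg.cholesky(R_pos)
    rng = np.random.default_rng([int(spec.seed) % (2**31), 29])
    subjects: list[Subject] = []
    plan = [(+1, spec.n_group_pos, L_pos, "pos"), (-1, spec.n_group_neg, L_neg, "neg")]
    for label, count, L, tag in plan:
        for k in range(count):
            z = rng.standard_normal((spec.n_timepoints, spec.n_regions))
            x = z @ L.T
            if spec.noise_sd > 0:
                x = x + spec.noise_sd * rng.standard_normal(x.shape)
            subjects.append(Subject(f"sub-{tag}-{k + 1:03d}", label, x))
    return TimeSeriesCohort(tuple(subjects), default_region_names(spec.n_regions))


def write_cohort(
    cohort: TimeSeriesCohort, directory: str | Path, overwrite: bool = False
) -> Path:
    """Write one TSV per subject plus a ``manifest.csv`` and return its path.

    Values are written with 17 significant digits so the round trip through
    :func:`mkfbn.io.read_cohort` is exact.
    """
    if len(cohort) == 0:
        raise ValueError("cannot write an empty cohort")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / "manifest.csv"
    if manifest.exists() and not overwrite:
        raise FileExistsError(
            f"{manifest} already exists; pass overwrite=True to replace it"
        )
    rows = []
    for s in cohort.subjects:
        rel = f"{s.subject_id}.tsv"
        df = pd.DataFrame(s.data, columns=list(cohort.region_names))
        df.to_csv(directory / rel, sep="\t", index=False, float_format="%.17g")
        rows.append({"subject_id": s.subject_id, "path": rel, "label": s.label})
    pd.DataFrame(rows).to_csv(manifest, index=False, quoting=csv.QUOTE_MINIMAL)
    return manifest
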