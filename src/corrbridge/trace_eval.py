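"""Traceable-length evaluation of neurite tracings against a reference.

A test tracing (e.g. from X-ray tomography) and a reference tracing (e.g.
an EM consensus warped into the same space) are both resampled at a fixed
arc step.  For every test point the distance to the nearest reference
point is recorded; the tracing counts as "lost" at the first point whose
distance exceeds the lost threshold (12 um for olfactory-bulb mitral
cells, 6 um for hippocampal CA1), and the arc position of that point is
the traceable length.  Tracings correctly followed for at least the
linkage threshold (35 um) are "linked": losses before that point reflect
the difficult soma-to-dendrite linkage region rather than dendrite-level
tracing failure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .skeletons import ResampledPath, SkeletonTree

__all__ = [
    "EvalParams",
    "DistanceProfile",
    "TraceEvalResult",
    "CohortSummary",
    "distance_profile",
    "traceable_length",
    "classify_trace",
    "select_consensus",
    "cohort_summary",
    "evaluate_pair",
]

STATUS_LINKED_KEPT = "linked_kept"
STATUS_LINKED_LOST = "linked_lost"
STATUS_LOST_AT_LINKAGE = "lost_at_linkage"
STATUS_TOO_SHORT = "too_short"


@dataclass(frozen=True)
class EvalParams:
    """Evaluation thresholds in nm.

    Defaults follow the olfactory-bulb protocol: 320 nm resampling step,
    12 um lost threshold, 35 um linkage threshold.  Hippocampal analyses
    use a 6 um lost threshold (thinner, more parallel dendrites).
    """

    spacing: float = 320.0
    lost_threshold: float = 12_000.0
    link_threshold: float = 35_000.0
    min_run_length: int = 1  # consecutive above-threshold samples required

    def __post_init__(self):
        if min(self.spacing, self.lost_threshold, self.link_threshold) <= 0:
            raise ValueError("all thresholds must be positive")
        if self.lost_threshold <= self.spacing:
            raise ValueError("lost_threshold must exceed the resampling spacing")

    @classmethod
    def hippocampus(cls) -> "EvalParams":
        return cls(lost_threshold=6_000.0)


@dataclass
class DistanceProfile:
    """Nearest-reference distance as a function of arc position on the test path."""

    arc_positions: np.ndarray  # nm, strictly increasing
    distances: np.ndarray      # nm

    def __post_init__(self):
        self.arc_positions = np.asarray(self.arc_positions, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.arc_positions.shape != self.distances.shape:
            raise ValueError("arc_positions and distances must match")
        if len(self.arc_positions) and np.any(np.diff(self.arc_positions) <= 0):
            raise ValueError("arc_positions must be strictly increasing")

    @property
    def total_length(self) -> float:
        return float(self.arc_positions[-1])


@dataclass
class TraceEvalResult:
    cell_id: str
    tracer_id: str
    traceable_length: float  # nm
    lost: bool
    lost_position: float | None  # nm, == traceable_length when lost
    status: str | None = None


@dataclass
class CohortSummary:
    """Cohort statistics over traceable lengths (all values nm)."""

    per_tracer_mean: dict[str, float]
    cross_tracer_mean: float
    cross_tracer_sem: float
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    counts_per_status: dict[str, int]
    n: int


def distance_profile(test: ResampledPath, reference: ResampledPath) -> DistanceProfile:
    """Per-test-point Euclidean distance to the nearest reference point.

    Exact nearest neighbour via a k-d tree (identical to brute force).
    """
    if len(test) == 0 or len(reference) == 0:
        raise ValueError("empty path")
    d, _ = cKDTree(reference.points).query(test.points, k=1)
    return DistanceProfile(test.cumulative_arc_length.copy(), d)


def traceable_length(
    profile: DistanceProfile, params: EvalParams, cell_id: str = "", tracer_id: str = ""
) -> TraceEvalResult:
    """First-exceedance rule: lost at the first sample above the threshold.

    ``params.min_run_length > 1`` requires that many consecutive
    above-threshold samples (debouncing); the loss is still placed at the
    first sample of the run.
    """
    above = profile.distances > params.lost_threshold
    idx = None
    if params.min_run_length <= 1:
        hits = np.flatnonzero(above)
        idx = int(hits[0]) if len(hits) else None
    else:
        run = 0
        for i, a in enumerate(above):
            run = run + 1 if a else 0
            if run >= params.min_run_length:
                idx = i - params.min_run_length + 1
                break
    if idx is None:
        return TraceEvalResult(cell_id, tracer_id, profile.total_length, False, None)
    pos = float(profile.arc_positions[idx])
    return TraceEvalResult(cell_id, tracer_id, pos, True, pos)


def classify_trace(
    result: TraceEvalResult, total_test_length: float, params: EvalParams
) -> str:
    """Assign the four-way status used for cohort splits."""
    if result.lost:
        status = (
            STATUS_LINKED_LOST
            if result.lost_position >= params.link_threshold
            else STATUS_LOST_AT_LINKAGE
        )
    else:
        status = (
            STATUS_LINKED_KEPT
            if total_test_length >= params.link_threshold
            else STATUS_TOO_SHORT
        )
    result.status = status
    return status


def evaluate_pair(
    test: ResampledPath,
    reference: ResampledPath,
    params: EvalParams,
    cell_id: str = "",
    tracer_id: str = "",
) -> TraceEvalResult:
    """distance_profile -> traceable_length -> classify_trace in one call."""
    profile = distance_profile(test, reference)
    result = traceable_length(profile, params, cell_id, tracer_id)
    classify_trace(result, test.total_length, params)
    return result


def select_consensus(
    trees: Sequence[SkeletonTree], correct_flags: Sequence[bool]
) -> SkeletonTree:
    """The longest correctly-traced tree (ties go to input order)."""
    candidates = [t for t, ok in zip(trees, correct_flags) if ok]
    if not candidates:
        raise ValueError("no correctly traced trees")
    best = candidates[0]
    for t in candidates[1:]:
        if t.cable_length() > best.cable_length():
            best = t
    return best


def cohort_summary(
    results: Iterable[TraceEvalResult],
    exclude_statuses: set[str] = frozenset(),
) -> CohortSummary:
    """Per-tracer means, cross-tracer mean +/- SEM, and pooled box statistics.

    Box statistics use the 1.5x interquartile-range outlier rule: whiskers
    extend to the most extreme points within [Q1 - 1.5 IQR, Q3 + 1.5 IQR].
    """
    kept = [r for r in results if r.status not in exclude_statuses]
    if not kept:
        raise ValueError("no results after exclusion")
    lengths = np.array([r.traceable_length for r in kept])
    by_tracer: dict[str, list[float]] = {}
    for r in kept:
        by_tracer.setdefault(r.tracer_id, []).append(r.traceable_length)
    tracer_means = {t: float(np.mean(v)) for t, v in by_tracer.items()}
    means = np.array(list(tracer_means.values()))
    sem = float(np.std(means, ddof=1) / np.sqrt(len(means))) if len(means) > 1 else 0.0

    q1, med, q3 = np.percentile(lengths, [25, 50, 75])
    iqr = q3 - q1
    inliers = lengths[(lengths >= q1 - 1.5 * iqr) & (lengths <= q3 + 1.5 * iqr)]
    counts: dict[str, int] = {}
    for r in kept:
        counts[r.status or "unclassified"] = counts.get(r.status or "unclassified", 0) + 1
    return CohortSummary(
        per_tracer_mean=tracer_means,
        cross_tracer_mean=float(means.mean()),
        cross_tracer_sem=sem,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inliers.min()),
        whisker_high=float(inliers.max()),
        counts_per_status=counts,
        n=len(kept),
    )
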