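"""Trajectory-class modeling: cluster, template, assign.

Complete-case longitudinal score matrices (subjects × visit-grid months)
are grouped by agglomerative clustering with Ward's linkage on Euclidean
distance. Per-cluster mean scores at each month form trajectory templates
— prototypes of, e.g., "stable" vs "decline" progression. Any subject with
at least three scored visits spanning more than a year can then be given a
prognostic label by Euclidean proximity to each template sampled at that
subject's available months, so incomplete visit schedules need no
imputation and no fixed prediction window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .cohort import (
    Cohort,
    SubjectRecord,
    SCALE_RANGES,
    INCREASING_SEVERITY_SCALES,
    CohortValidationError,
)

#: Canonical class names by cluster count, ordered least→most severe.
DEFAULT_CLASS_LABELS = {
    2: ("stable", "decline"),
    3: ("stable", "slow_decline", "fast_decline"),
}

#: A subject visit within this many months of a grid month maps onto it.
GRID_SNAP_TOLERANCE = 3


@dataclass
class TrajectoryTemplate:
    """Per-class mean score at each month of a fixed visit grid."""

    scale: str
    months: list[int]
    class_labels: list[str]
    means: np.ndarray  # (n_classes, n_months)
    n_per_class: list[int]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        if self.means.shape != (len(self.class_labels), len(self.months)):
            raise ValueError("means shape does not match class_labels × months")

    def to_json(self) -> str:
        d = {
            "scale": self.scale,
            "months": list(map(int, self.months)),
            "class_labels": list(self.class_labels),
            "means": self.means.tolist(),
            "n_per_class": list(map(int, self.n_per_class)),
            "provenance": self.provenance,
        }
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TrajectoryTemplate":
        d = json.loads(text)
        return cls(
            scale=d["scale"], months=d["months"], class_labels=d["class_labels"],
            means=np.asarray(d["means"]), n_per_class=d["n_per_class"],
            provenance=d.get("provenance", {}),
        )


@dataclass
class TrajectoryAssignment:
    """Class label for one subject plus the evidence used."""

    subject_id: str
    label: str
    distances: dict[str, float]
    months_used: list[int]
    span_months: int


def cluster_trajectories(score_matrix: np.ndarray, k: int) -> np.ndarray:
    """Ward-linkage agglomerative clustering of complete score trajectories.

    Parameters
    ----------
    score_matrix : (n_subjects, n_months) array, no missing entries
    k : number of clusters to cut the dendrogram at

    Returns integer cluster labels in [0, k). Deterministic for fixed input.
    """
    X = np.asarray(score_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("score_matrix must be 2-D (subjects × months)")
    if np.any(np.isnan(X)):
        raise ValueError(
            "score_matrix contains missing entries; clustering requires "
            "complete-case input — select subjects with scores at every grid month"
        )
    n = X.shape[0]
    if k < 2:
        raise ValueError("k must be ≥ 2")
    if n <= k:
        raise ValueError(f"need more subjects ({n}) than clusters ({k})")
    Z = linkage(X, method="ward", metric="euclidean")
    return fcluster(Z, t=k, criterion="maxclust") - 1


def _severity_key(mean_row: np.ndarray, scale: str) -> float:
    """Sort key putting the least severe class first (final-month severity)."""
    final = float(mean_row[-1])
    return final if scale in INCREASING_SEVERITY_SCALES else -final


def build_templates(
    score_matrix: np.ndarray,
    cluster_labels: Sequence[int],
    months: Sequence[int],
    scale: str,
    class_labels: Optional[Sequence[str]] = None,
    provenance: Optional[dict] = None,
) -> TrajectoryTemplate:
    """Average each cluster's scores at each month into a template.

    Classes are reordered canonically by final-month severity (least severe
    first) so "stable"/"decline" naming is reproducible across runs.
    """
    X = np.asarray(score_matrix, dtype=float)
    lab = np.asarray(cluster_labels)
    uniq = np.unique(lab)
    counts = {int(u): int(np.sum(lab == u)) for u in uniq}
    if min(counts.values()) == 0 or len(uniq) < 2:
        raise ValueError("each cluster must be non-empty and k ≥ 2")
    means = np.stack([X[lab == u].mean(axis=0) for u in uniq])
    order = np.argsort([_severity_key(means[i], scale) for i in range(len(uniq))])
    means = means[order]
    n_per = [counts[int(uniq[i])] for i in order]
    if class_labels is None:
        class_labels = DEFAULT_CLASS_LABELS.get(len(uniq), tuple(f"class_{i}" for i in range(len(uniq))))
    return TrajectoryTemplate(
        scale=scale,
        months=[int(m) for m in months],
        class_labels=list(class_labels),
        means=means,
        n_per_class=n_per,
        provenance=provenance or {},
    )


def _match_months(subject: SubjectRecord, template: TrajectoryTemplate) -> tuple[list[int], list[float]]:
    """Pair the subject's scored visits with template grid months.

    A visit within ±GRID_SNAP_TOLERANCE months of a grid month is snapped
    onto it (scheduled-visit windows); visits farther off-grid are ignored.
    Each grid month is used at most once (the closest visit wins).
    """
    grid = np.asarray(template.months)
    pairs: dict[int, tuple[int, float]] = {}  # grid_idx -> (|offset|, score)
    for v in subject.visits:
        s = v.score(template.scale)
        if s is None:
            continue
        j = int(np.argmin(np.abs(grid - v.month)))
        off = abs(int(grid[j]) - v.month)
        if off <= GRID_SNAP_TOLERANCE and (j not in pairs or off < pairs[j][0]):
            pairs[j] = (off, float(s))
    idx = sorted(pairs)
    return idx, [pairs[j][1] for j in idx]


def assign_trajectory(subject: SubjectRecord, template: TrajectoryTemplate) -> TrajectoryAssignment:
    """Label a subject by Euclidean proximity to each template.

    Distances use the template means restricted to the subject's available
    grid months (unnormalized Euclidean — comparison is within-subject
    across classes, so the month count cancels). Ties break toward the less
    severe class, i.e. the earlier class in canonical order.
    """
    idx, scores = _match_months(subject, template)
    months_used = [template.months[j] for j in idx]
    if len(months_used) < 3:
        raise CohortValidationError(
            f"subject {subject.subject_id}: only {len(months_used)} usable "
            f"timepoints on the template grid (need ≥ 3)"
        )
    span = max(months_used) - min(months_used)
    if span <= 12:
        raise CohortValidationError(
            f"subject {subject.subject_id}: timespan {span} months not > 12"
        )
    s = np.asarray(scores)
    dists = {
        label: float(np.linalg.norm(s - template.means[c, idx]))
        for c, label in enumerate(template.class_labels)
    }
    # argmin with ties toward the less severe class = first in canonical order
    best = min(template.class_labels, key=lambda L: (dists[L],))
    return TrajectoryAssignment(
        subject_id=subject.subject_id,
        label=best,
        distances=dists,
        months_used=months_used,
        span_months=int(span),
    )


def label_cohort(
    cohort: Cohort, template: TrajectoryTemplate
) -> tuple[list[TrajectoryAssignment], list[tuple[str, str]]]:
    """Assign every eligible subject; report ineligible ones with reasons.

    Returns (assignments, ineligible) where ineligible is a list of
    (subject_id, reason). Per-subject failures are reported, not raised.
    """
    assignments = []
    ineligible = []
    for s in cohort.subjects:
        try:
            assignments.append(assign_trajectory(s, template))
        except CohortValidationError as e:
            ineligible.append((s.subject_id, str(e)))
    return assignments, ineligible


def complete_case_matrix(
    cohort: Cohort, scale: str, months: Sequence[int]
) -> tuple[np.ndarray, list[str]]:
    """Score matrix of subjects with a score at every grid month.

    The clustering step requires fully observed trajectories; this selects
    them and returns (matrix, subject_ids).
    """
    rows, ids = [], []
    for s in cohort.subjects:
        by_month = {v.month: v.score(scale) for v in s.visits if v.score(scale) is not None}
        if all(m in by_month for m in months):
            rows.append([by_month[m] for m in months])
            ids.append(s.subject_id)
    if not rows:
        return np.empty((0, len(months))), ids
    return np.asarray(rows, dtype=float), ids


def model_trajectories(
    cohort: Cohort,
    scale: str,
    k: int,
    months: Sequence[int],
    seed: Optional[int] = None,
) -> tuple[TrajectoryTemplate, dict[str, str]]:
    """Cluster the complete cases and build the template in one call.

    Returns (template, subject_id → cluster label for the training subjects).
    ``seed`` is recorded in provenance only; Ward clustering is deterministic.
    """
    X, ids = complete_case_matrix(cohort, scale, months)
    labels = cluster_trajectories(X, k)
    template = build_templates(
        X, labels, months, scale,
        provenance={"k": k, "n_complete_cases": len(ids),
                    "linkage": "ward", "metric": "euclidean",
                    "seed": seed},
    )
    # map raw cluster ids to canonical class labels via per-cluster means
    raw_means = {u: X[labels == u].mean(axis=0) for u in np.unique(labels)}
    canon = {}
    for u, m in raw_means.items():
        c = int(np.argmin(np.linalg.norm(template.means - m[None, :], axis=1)))
        canon[u] = template.class_labels[c]
    return template, {sid: canon[int(l)] for sid, l in zip(ids, labels)}
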