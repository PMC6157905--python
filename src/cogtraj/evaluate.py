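"""Nested stratified cross-validation harness and evaluation metrics.

Outer folds estimate performance; inner folds (inside each outer training
set) drive hyperparameter selection, so no test subject influences any
training decision. Folds are stratified jointly on source-cohort tag and
trajectory class. Metrics: accuracy, AUC (binary; macro one-vs-rest for
three classes, an extension beyond the accuracy-only three-way reporting),
confusion matrix, and ROC points. Model contrasts use the two-sided
Mann-Whitney U test over per-fold metric samples.

Subject-group stratifications:

* clinical workflow — baseline edge-cases (BE, extreme baseline score),
  follow-up edge-cases (FE, marked short-term change), cognitively
  consistent (CC, neither): the CC group is where clinical scores are
  least informative and structural change must carry the prediction;
* timepoint span — near-future (last ground-truth visit ≤ 36 months) vs
  distant-future (48–72 months) label provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy.stats import mannwhitneyu
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .cohort import Cohort, SubjectRecord, SCALE_RANGES
from .lsn import LSNConfig, PredictionInput, predict_proba, train_lsn
from .reference import (
    DEFAULT_GRIDS,
    FAST_GRIDS,
    FeatureSpec,
    build_feature_matrix,
    fit_reference,
)
from .trajectory import TrajectoryAssignment

# ---------------------------------------------------------------------------
# Second-timepoint selection and input assembly


def select_followup(subject: SubjectRecord, scale: str, window_months: int = 12):
    """Latest visit within (0, window_months] with both score and CT.

    The prediction model is agnostic to the exact interval, so a subject
    missing the 12-month visit but complete at 6 months is still usable.
    Returns the VisitRecord or None (subject then excluded from
    two-timepoint analyses).
    """
    best = None
    for v in subject.visits:
        if 0 < v.month <= window_months and v.score(scale) is not None and v.ct is not None:
            best = v  # visits are month-sorted; last hit is the latest
    return best


def build_prediction_inputs(
    cohort: Cohort, scale: str, window_months: int = 12
) -> tuple[list[PredictionInput], list[str], list[tuple[str, str]]]:
    """Two-timepoint feature bundles for every usable subject.

    Requires a complete baseline (score + CT at month 0) and a follow-up
    from :func:`select_followup`. Returns (inputs, subject_ids, excluded)
    with exclusion reasons.
    """
    inputs, ids, excluded = [], [], []
    for s in cohort.subjects:
        b = s.baseline()
        if b.score(scale) is None or b.ct is None:
            excluded.append((s.subject_id, "incomplete baseline (score or CT missing)"))
            continue
        f = select_followup(s, scale, window_months)
        if f is None:
            excluded.append((s.subject_id, f"no complete follow-up within {window_months} months"))
            continue
        inputs.append(
            PredictionInput(
                ct_t0=b.ct, ct_t1=f.ct,
                score_t0=float(b.score(scale)), score_t1=float(f.score(scale)),
                age=s.age, apoe4=s.apoe4,
            )
        )
        ids.append(s.subject_id)
    return inputs, ids, excluded


# ---------------------------------------------------------------------------
# Fold construction


@dataclass
class Fold:
    train_idx: np.ndarray
    test_idx: np.ndarray
    inner: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)


def nested_cv_split(
    labels: Sequence[int],
    cohort_tags: Optional[Sequence[str]] = None,
    k: int = 10,
    inner_k: int = 5,
    seed: int = 0,
) -> list[Fold]:
    """Outer folds stratified jointly on (cohort tag × class), nested inner.

    Inner folds are drawn within each outer training set under the same
    joint stratification. Deterministic given the seed.
    """
    y = np.asarray(labels)
    n = len(y)
    tags = np.asarray(cohort_tags) if cohort_tags is not None else np.array(["_"] * n)
    joint = np.array([f"{t}|{c}" for t, c in zip(tags, y)])
    _, counts = np.unique(joint, return_counts=True)
    if counts.min() < k:
        u = np.unique(joint)[np.argmin(counts)]
        raise ValueError(
            f"stratum {u!r} has {counts.min()} subjects, fewer than k={k} folds"
        )
    outer = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for f, (tr, te) in enumerate(outer.split(np.zeros(n), joint)):
        inner_splits = []
        inner_joint = joint[tr]
        if inner_k >= 2 and np.unique(inner_joint, return_counts=True)[1].min() >= inner_k:
            inner = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=seed + 1000 + f)
            inner_splits = [(tr[i], tr[v]) for i, v in inner.split(np.zeros(len(tr)), inner_joint)]
        folds.append(Fold(train_idx=tr, test_idx=te, inner=inner_splits))
    return folds


# ---------------------------------------------------------------------------
# Metrics


@dataclass
class Metrics:
    accuracy: float
    auc: Optional[float]
    confusion: np.ndarray  # rows = true classes
    roc: Optional[dict]    # binary only: fpr/tpr/thresholds lists
    n: int


def compute_metrics(
    y_true: Sequence[int],
    y_pred: Sequence[int],
    scores: Optional[np.ndarray] = None,
    n_classes: Optional[int] = None,
) -> Metrics:
    """Accuracy, AUC, confusion matrix, and ROC points.

    Binary AUC is the probability that a random positive outscores a random
    negative (ties count one half). Three-class AUC is macro-averaged
    one-vs-rest. With a single-class truth the AUC is undefined and
    reported as None, never 0.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if n_classes is None:
        n_classes = int(max(y_true.max(), y_pred.max())) + 1
    acc = float(np.mean(y_true == y_pred))
    cm = _sk_confusion(y_true, y_pred, labels=np.arange(n_classes))
    auc = None
    roc = None
    if scores is not None and len(np.unique(y_true)) >= 2:
        scores = np.asarray(scores, dtype=float)
        if n_classes == 2:
            pos = scores[:, 1] if scores.ndim == 2 else scores
            auc = float(roc_auc_score(y_true, pos))
            fpr, tpr, thr = roc_curve(y_true, pos)
            roc = {"fpr": fpr.tolist(), "tpr": tpr.tolist(), "thresholds": thr.tolist()}
        else:
            present = np.unique(y_true)
            if len(present) == n_classes:
                auc = float(roc_auc_score(y_true, scores, multi_class="ovr", average="macro"))
            else:  # macro over the one-vs-rest tasks that are defined
                aucs = [roc_auc_score((y_true == c).astype(int), scores[:, c]) for c in present]
                auc = float(np.mean(aucs))
    return Metrics(accuracy=acc, auc=auc, confusion=cm, roc=roc, n=len(y_true))


# ---------------------------------------------------------------------------
# Subject-group stratifications


@dataclass
class WorkflowThresholds:
    """Cutoffs defining the BE/FE/CC clinical-workflow groups.

    The defaults below are illustrative placeholders on each scale —
    review them for any concrete deployment; the grouping is a use-case
    demonstration, not a fixed clinical rule.
    """

    low_baseline: float
    high_baseline: float
    followup_change: float

    def validate(self, scale: str) -> None:
        lo, hi = SCALE_RANGES[scale]
        if not (lo <= self.low_baseline < self.high_baseline <= hi):
            raise ValueError(f"baseline cutoffs outside {scale} range [{lo}, {hi}]")
        if self.followup_change <= 0:
            raise ValueError("followup_change cutoff must be > 0")


DEFAULT_WORKFLOW_THRESHOLDS = {
    "mmse": WorkflowThresholds(low_baseline=24.0, high_baseline=29.0, followup_change=2.0),
    "adas13": WorkflowThresholds(low_baseline=10.0, high_baseline=30.0, followup_change=4.0),
}


def stratify_clinical_workflow(
    score_t0: float,
    score_t1: float,
    scale: str,
    thresholds: Optional[WorkflowThresholds] = None,
) -> str:
    """Map one subject to exactly one of {BE, FE, CC}.

    BE: baseline score outside [low, high] (extreme performance — the
    clinical picture alone is decisive). Else FE: absolute short-term
    change ≥ the change cutoff. Else CC.
    """
    t = thresholds or DEFAULT_WORKFLOW_THRESHOLDS[scale]
    t.validate(scale)
    if not (t.low_baseline <= score_t0 <= t.high_baseline):
        return "BE"
    if abs(score_t1 - score_t0) >= t.followup_change:
        return "FE"
    return "CC"


def stratify_by_span(
    assignments: Sequence[TrajectoryAssignment],
    near_max_month: int = 36,
    far_min_month: int = 48,
) -> dict[str, Optional[str]]:
    """Group subjects by the last visit used for their ground-truth label.

    ≤ near_max_month → "near_future"; ≥ far_min_month → "distant_future";
    the (near_max, far_min) gap maps to None (flagged, in neither band).
    """
    out: dict[str, Optional[str]] = {}
    for a in assignments:
        last = max(a.months_used)
        if last <= near_max_month:
            out[a.subject_id] = "near_future"
        elif last >= far_min_month:
            out[a.subject_id] = "distant_future"
        else:
            out[a.subject_id] = None
    return out


# ---------------------------------------------------------------------------
# Model comparison


def compare_models(sample_a: Sequence[float], sample_b: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value over per-fold metric samples.

    Exact null for small samples (n ≤ 10 per side, no ties), normal
    approximation with tie correction otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 per-fold samples per model")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) <= 10 and len(b) <= 10 and not ties) else "asymptotic"
    return float(mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


# ---------------------------------------------------------------------------
# Experiment driver


@dataclass
class CellResult:
    """All outputs for one (model, feature set, timepoint set) design cell."""

    model: str
    feature_set: str
    timepoints: str
    fold_accuracy: list[float]
    fold_auc: list[Optional[float]]
    pooled_confusion: np.ndarray
    pooled_roc: Optional[dict]
    subject_ids: list[str]
    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray  # (n, n_classes)
    fold_of_subject: np.ndarray
    error: Optional[str] = None


@dataclass
class EvaluationReport:
    scale: str
    class_names: list[str]
    k: int
    seed: int
    cells: dict[str, CellResult] = field(default_factory=dict)
    comparisons: dict[str, float] = field(default_factory=dict)
    fold_membership: dict[str, list[list[str]]] = field(default_factory=dict)

    @staticmethod
    def cell_key(model: str, spec: FeatureSpec) -> str:
        return f"{model}|{spec.feature_set}|{spec.timepoints}"

    def group_metrics(self, key: str, groups: dict[str, str]) -> dict[str, Metrics]:
        """Re-aggregate a cell's stored predictions within subject groups."""
        cell = self.cells[key]
        out = {}
        for gname in sorted(set(g for g in groups.values() if g is not None)):
            mask = np.array([groups.get(sid) == gname for sid in cell.subject_ids])
            if mask.sum() == 0:
                continue
            out[gname] = compute_metrics(
                cell.y_true[mask], cell.y_pred[mask], cell.scores[mask],
                n_classes=len(self.class_names),
            )
        return out

    def to_json(self) -> str:
        def cell_doc(c: CellResult) -> dict:
            return {
                "model": c.model, "feature_set": c.feature_set, "timepoints": c.timepoints,
                "fold_accuracy": c.fold_accuracy, "fold_auc": c.fold_auc,
                "pooled_confusion": c.pooled_confusion.tolist(),
                "pooled_roc": c.pooled_roc,
                "subject_ids": c.subject_ids,
                "y_true": c.y_true.tolist(), "y_pred": c.y_pred.tolist(),
                "scores": np.round(c.scores, 12).tolist(),
                "fold_of_subject": c.fold_of_subject.tolist(),
                "error": c.error,
            }
        doc = {
            "scale": self.scale, "class_names": self.class_names,
            "k": self.k, "seed": self.seed,
            "cells": {k: cell_doc(c) for k, c in sorted(self.cells.items())},
            "comparisons": dict(sorted(self.comparisons.items())),
            "fold_membership": self.fold_membership,
        }
        return json.dumps(doc, indent=1, sort_keys=True)


def _fit_predict_cell(
    model: str,
    spec: FeatureSpec,
    inputs: list[PredictionInput],
    y: np.ndarray,
    folds: list[Fold],
    n_classes: int,
    seed: int,
    grids: Optional[dict],
    lsn_config: Optional[LSNConfig],
    inner_folds: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Outer-fold loop for one cell: returns (y_pred, scores, fold_id)."""
    n = len(inputs)
    y_pred = np.full(n, -1, dtype=int)
    scores = np.zeros((n, n_classes))
    fold_id = np.full(n, -1, dtype=int)
    def fold_seed(f: int) -> int:
        return (seed * 1000 + f) % (2**31 - 1)

    if model == "LSN":
        for f, fold in enumerate(folds):
            cfg_f = LSNConfig(**{**asdict(lsn_config), "seed": fold_seed(f),
                                 "n_classes": n_classes})
            tr_inputs = [inputs[i] for i in fold.train_idx]
            params, _ = train_lsn(tr_inputs, y[fold.train_idx], cfg_f)
            p = predict_proba(params, [inputs[i] for i in fold.test_idx])
            scores[fold.test_idx] = p
            y_pred[fold.test_idx] = np.argmax(p, axis=1)
            fold_id[fold.test_idx] = f
    else:
        X = build_feature_matrix(inputs, spec)
        grid = (grids or DEFAULT_GRIDS)[model]
        for f, fold in enumerate(folds):
            fitted = fit_reference(
                model, X[fold.train_idx], y[fold.train_idx],
                grid=grid, inner_folds=inner_folds, seed=fold_seed(f),
            )
            sc = fitted.decision_scores(X[fold.test_idx])
            scores[fold.test_idx] = sc
            y_pred[fold.test_idx] = fitted.predict(X[fold.test_idx])
            fold_id[fold.test_idx] = f
    return y_pred, scores, fold_id


def run_experiment(
    inputs: list[PredictionInput],
    subject_ids: list[str],
    labels: Sequence[int],
    class_names: Sequence[str],
    scale: str,
    cohort_tags: Optional[Sequence[str]] = None,
    models: Sequence[str] = ("LR", "SVM", "RF", "ANN", "LSN"),
    feature_specs: Optional[Sequence[FeatureSpec]] = None,
    k: int = 10,
    inner_folds: int = 5,
    seed: int = 0,
    grids: Optional[dict] = None,
    lsn_config: Optional[LSNConfig] = None,
) -> EvaluationReport:
    """Full factorial run: models × feature specs × timepoint sets.

    The Siamese model applies only to the two-timepoint CA+CT cell (its
    architecture requires both CT vectors plus the clinical stream); the
    reference models run on every requested cell. Per-cell failures are
    recorded on the cell, the run continues. Deterministic given ``seed``.
    """
    y = np.asarray(labels, dtype=int)
    n_classes = len(class_names)
    if feature_specs is None:
        feature_specs = [
            FeatureSpec(fs, tp, scale)
            for tp in ("baseline", "baseline_followup")
            for fs in ("CA", "CT", "CA_CT")
        ]
    folds = nested_cv_split(y, cohort_tags, k=k, inner_k=inner_folds, seed=seed)
    report = EvaluationReport(scale=scale, class_names=list(class_names), k=k, seed=seed)
    report.fold_membership = {
        "test": [[subject_ids[i] for i in f.test_idx] for f in folds]
    }
    if lsn_config is None:
        lsn_config = LSNConfig(n_classes=n_classes)

    for model in models:
        specs = feature_specs
        if model == "LSN":
            specs = [s for s in feature_specs
                     if s.feature_set == "CA_CT" and s.timepoints == "baseline_followup"]
        for spec in specs:
            key = EvaluationReport.cell_key(model, spec)
            try:
                y_pred, scores, fold_id = _fit_predict_cell(
                    model, spec, inputs, y, folds, n_classes, seed, grids,
                    lsn_config, inner_folds,
                )
            except Exception as e:  # per-cell failure: log and continue
                report.cells[key] = CellResult(
                    model=model, feature_set=spec.feature_set, timepoints=spec.timepoints,
                    fold_accuracy=[], fold_auc=[], pooled_confusion=np.zeros((n_classes, n_classes), dtype=int),
                    pooled_roc=None, subject_ids=[], y_true=np.array([]), y_pred=np.array([]),
                    scores=np.empty((0, n_classes)), fold_of_subject=np.array([]),
                    error=f"{type(e).__name__}: {e}",
                )
                continue
            fold_acc, fold_auc = [], []
            pooled_cm = np.zeros((n_classes, n_classes), dtype=int)
            for f, fold in enumerate(folds):
                m = compute_metrics(y[fold.test_idx], y_pred[fold.test_idx],
                                    scores[fold.test_idx], n_classes=n_classes)
                fold_acc.append(m.accuracy)
                fold_auc.append(m.auc)
                pooled_cm += m.confusion
            overall = compute_metrics(y, y_pred, scores, n_classes=n_classes)
            report.cells[key] = CellResult(
                model=model, feature_set=spec.feature_set, timepoints=spec.timepoints,
                fold_accuracy=fold_acc, fold_auc=fold_auc,
                pooled_confusion=pooled_cm, pooled_roc=overall.roc,
                subject_ids=list(subject_ids), y_true=y.copy(), y_pred=y_pred,
                scores=scores, fold_of_subject=fold_id,
            )

    # Mann-Whitney contrasts of the Siamese cell against each reference
    # model's two-timepoint CA+CT cell, on per-fold AUC and accuracy.
    lsn_key = "LSN|CA_CT|baseline_followup"
    if lsn_key in report.cells and not report.cells[lsn_key].error:
        for model in models:
            if model == "LSN":
                continue
            other = f"{model}|CA_CT|baseline_followup"
            if other in report.cells and not report.cells[other].error:
                a, b = report.cells[lsn_key], report.cells[other]
                report.comparisons[f"LSN_vs_{model}|accuracy"] = compare_models(
                    a.fold_accuracy, b.fold_accuracy)
                if all(v is not None for v in a.fold_auc + b.fold_auc):
                    report.comparisons[f"LSN_vs_{model}|auc"] = compare_models(
                        [v for v in a.fold_auc], [v for v in b.fold_auc])
    return report
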