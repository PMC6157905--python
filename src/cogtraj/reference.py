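"""Reference classifiers on concatenated feature vectors.

The comparison baselines: logistic regression with a lasso penalty (LR),
support vector machine (SVM), random forest (RF), and a plain feed-forward
neural network (ANN). Each consumes a single flat concatenation of the
selected features — no Siamese structure, no multiplicative modulation —
which is exactly the architectural contrast the two-timepoint Siamese
model is evaluated against.

Feature design: two timepoint sets (baseline only, baseline + follow-up)
crossed with three feature sets — clinical attributes (CA: score(s), age,
APOE4), cortical thickness (CT: 78 or 156 ROI values), and their
combination (CA+CT). LR and SVM inputs are z-scored with statistics from
the training fold only; RF is scale-invariant and left raw. The ANN also
receives train-fold z-scored input for trainability (a documented
deviation from leaving it raw).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .lsn import PredictionInput

FeatureSet = Literal["CA", "CT", "CA_CT"]
TimepointSet = Literal["baseline", "baseline_followup"]

MODEL_KINDS = ("LR", "SVM", "RF", "ANN")
STANDARDIZED_KINDS = frozenset({"LR", "SVM", "ANN"})


@dataclass(frozen=True)
class FeatureSpec:
    feature_set: FeatureSet
    timepoints: TimepointSet
    scale: str = "mmse"

    def n_features(self, roi_count: int = 78) -> int:
        two = self.timepoints == "baseline_followup"
        n = 0
        if self.feature_set in ("CA", "CA_CT"):
            n += (2 if two else 1) + 2  # score(s) + age + apoe4
        if self.feature_set in ("CT", "CA_CT"):
            n += roi_count * (2 if two else 1)
        return n

    def describe(self) -> str:
        tp = "BL+FU" if self.timepoints == "baseline_followup" else "BL"
        return f"{self.feature_set}/{tp}/{self.scale}"


def make_feature_vector(x: PredictionInput, spec: FeatureSpec) -> np.ndarray:
    """Concatenate the requested features in fixed order.

    Order: [score_t0 (, score_t1), age, apoe4 (, ct_t0 (, ct_t1))].
    """
    two = spec.timepoints == "baseline_followup"
    parts: list[np.ndarray] = []
    if spec.feature_set in ("CA", "CA_CT"):
        scores = [x.score_t0, x.score_t1] if two else [x.score_t0]
        if any(s is None for s in scores):
            raise ValueError("missing clinical score required by feature spec")
        parts.append(np.array(scores + [x.age, float(x.apoe4)], dtype=float))
    if spec.feature_set in ("CT", "CA_CT"):
        if x.ct_t0 is None or (two and x.ct_t1 is None):
            raise ValueError("missing CT vector required by feature spec")
        parts.append(np.asarray(x.ct_t0, dtype=float))
        if two:
            parts.append(np.asarray(x.ct_t1, dtype=float))
    return np.concatenate(parts)


def build_feature_matrix(inputs: Sequence[PredictionInput], spec: FeatureSpec) -> np.ndarray:
    return np.stack([make_feature_vector(x, spec) for x in inputs])


def standardize_features(
    train: np.ndarray, test: Optional[np.ndarray] = None
) -> tuple[np.ndarray, Optional[np.ndarray], dict]:
    """Column z-scoring with train statistics applied to both matrices.

    Zero-variance columns map to 0 (with a warning) rather than dividing
    by zero.
    """
    train = np.asarray(train, dtype=float)
    if train.size == 0:
        raise ValueError("empty training matrix")
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    zero = sd <= 1e-12
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} constant feature column(s) standardized to 0",
            stacklevel=2,
        )
    safe_sd = np.where(zero, 1.0, sd)
    tr = (train - mean) / safe_sd
    tr[:, zero] = 0.0
    te = None
    if test is not None:
        te = (np.asarray(test, dtype=float) - mean) / safe_sd
        te[:, zero] = 0.0
    return tr, te, {"mean": mean, "sd": sd}


#: Inner-fold hyperparameter grids per model kind.
DEFAULT_GRIDS: dict[str, dict] = {
    "LR": {"C": [1e-3, 1e-2, 1e-1, 1.0, 10.0, 100.0]},
    "SVM": {
        "kernel": ["rbf", "linear"],
        "C": [1e-2, 1e-1, 1.0, 10.0, 100.0],
        "gamma": ["scale"],
    },
    "RF": {"n_estimators": [100, 500], "max_depth": [None, 5, 10]},
    "ANN": {"hidden_layer_sizes": [(25,), (50,), (25, 25), (50, 50)]},
}

#: Minimal grids for smoke runs and quick cross-validation cells.
FAST_GRIDS: dict[str, dict] = {
    "LR": {"C": [1.0]},
    "SVM": {"kernel": ["rbf"], "C": [1.0], "gamma": ["scale"]},
    "RF": {"n_estimators": [100], "max_depth": [None]},
    "ANN": {"hidden_layer_sizes": [(25,)]},
}


def _base_estimator(kind: str, seed: int):
    if kind == "LR":
        return LogisticRegression(penalty="l1", solver="saga", max_iter=5000,
                                  random_state=seed)
    if kind == "SVM":
        return SVC(random_state=seed)  # decision_function used for scores
    if kind == "RF":
        return RandomForestClassifier(random_state=seed)
    if kind == "ANN":
        return MLPClassifier(max_iter=1000, random_state=seed)
    raise ValueError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")


@dataclass
class FittedReference:
    """A fitted baseline plus the standardization it was trained under."""

    kind: str
    estimator: object
    chosen_params: dict
    stats: Optional[dict]  # z-scoring statistics, None if unstandardized

    def _transform(self, X: np.ndarray) -> np.ndarray:
        if self.stats is None:
            return np.asarray(X, dtype=float)
        sd = self.stats["sd"]
        zero = sd <= 1e-12
        safe = np.where(zero, 1.0, sd)
        Xs = (np.asarray(X, dtype=float) - self.stats["mean"]) / safe
        Xs[:, zero] = 0.0
        return Xs

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(self._transform(X))

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Monotone class scores for ROC/AUC.

        Probabilities where available; the SVM exposes decision-function
        values instead (monotone suffices for rank-based metrics).
        """
        Xs = self._transform(X)
        if hasattr(self.estimator, "predict_proba"):
            return self.estimator.predict_proba(Xs)
        scores = self.estimator.decision_function(Xs)
        if scores.ndim == 1:  # binary: column per class for uniform shape
            return np.column_stack([-scores, scores])
        return scores


def fit_reference(
    kind: str,
    X: np.ndarray,
    y: Sequence[int],
    grid: Optional[dict] = None,
    inner_folds: int = 5,
    seed: int = 0,
) -> FittedReference:
    """Fit one baseline with inner-fold grid search on training data only.

    Hyperparameters are chosen by mean inner-fold accuracy, the winner
    refit on all training rows. Standardization (for LR/SVM/ANN) uses
    statistics of the full training matrix; the caller applies the fitted
    model to test data through :meth:`FittedReference.predict`, which
    re-applies those statistics — no test information enters here.
    """
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if grid is None:
        grid = DEFAULT_GRIDS[kind]
    stats = None
    Xfit = np.asarray(X, dtype=float)
    if kind in STANDARDIZED_KINDS:
        Xfit, _, stats = standardize_features(Xfit)
    est = _base_estimator(kind, seed)
    n_candidates = int(np.prod([len(v) for v in grid.values()]))
    if n_candidates > 1:
        inner = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            search = GridSearchCV(est, grid, scoring="accuracy", cv=inner, n_jobs=1)
            search.fit(Xfit, y)
        chosen = search.best_params_
        est = search.best_estimator_
    else:
        chosen = {k: v[0] for k, v in grid.items()}
        est.set_params(**chosen)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(Xfit, y)
    return FittedReference(kind=kind, estimator=est, chosen_params=chosen, stats=stats)
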