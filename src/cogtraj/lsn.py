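"""Longitudinal Siamese Network (LSN).

A three-stage network for predicting a subject's trajectory class from two
timepoints of multimodal data:

1. *Siamese stage* — twin branches with a single shared parameter set (four
   rectifier hidden layers, then a linear map to the embedding) transform
   each timepoint's 78-ROI cortical-thickness vector; the signed difference
   of the branch outputs is the **distance embedding**, a learned
   representation of neuroanatomical change (atrophy) over the interval.
2. *Multiplicative modulation* — a one-node layer computes a logistic gate
   from the APOE4 allele count alone; the embedding is scaled elementwise
   by this scalar, encoding a non-additive interaction between structural
   change and genetic risk.
3. *Prediction head* — the modulated embedding is concatenated with the
   standardized baseline and follow-up clinical scores and age, passed
   through one rectifier hidden layer, and mapped to class probabilities
   by a softmax.

All parameters are learned jointly by Adam on the cross-entropy, with
early stopping on a validation split. The implementation is pure numpy
with explicit backpropagation; weight sharing is structural (one stored
branch serves both timepoints), so the antisymmetry
``embedding(x, y) = -embedding(y, x)`` holds exactly by construction.

Continuous inputs (thickness, scores, age) are standardized inside the
model with statistics fitted on the training set only; thickness
statistics are pooled over both timepoints per ROI so the shared branch
sees the two visits on a common scale and their difference keeps its
meaning as change.
"""

from __future__ import annotations

import base64
import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np


class LsnInputError(ValueError):
    pass


@dataclass
class LSNConfig:
    roi_count: int = 78
    branch_layers: int = 4
    branch_width: int = 35
    embedding_dim: int = 15
    head_width: int = 15
    n_classes: int = 2
    learning_rate: float = 1e-3
    weight_decay: float = 1e-3
    embedding_dropout: float = 0.5
    max_epochs: int = 300
    batch_size: int = 32
    early_stop_patience: int = 20
    validation_fraction: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.n_classes not in (2, 3):
            raise ValueError("n_classes must be 2 or 3")
        for name in ("roi_count", "branch_width", "embedding_dim", "head_width"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be ≥ 1")


#: Coarse hyperparameter grid over the architecture's searchable widths.
DEFAULT_GRID = {
    "branch_width": (25, 35, 50),
    "embedding_dim": (10, 15, 20),
    "head_width": (10, 15, 20),
}


@dataclass
class PredictionInput:
    """One subject's two-timepoint feature bundle."""

    ct_t0: np.ndarray
    ct_t1: np.ndarray
    score_t0: float
    score_t1: float
    age: float
    apoe4: int

    def validate(self, roi_count: int) -> None:
        if self.ct_t0 is None or self.ct_t1 is None:
            raise LsnInputError("LSN requires two timepoints: missing CT vector")
        if len(self.ct_t0) != roi_count or len(self.ct_t1) != roi_count:
            raise LsnInputError(
                f"CT vectors must have {roi_count} ROIs "
                f"(got {len(self.ct_t0)}, {len(self.ct_t1)})"
            )
        if self.apoe4 not in (0, 1, 2):
            raise LsnInputError(f"apoe4={self.apoe4} not in {{0,1,2}}")


@dataclass
class LSNParameters:
    """All learned parameters plus input-standardization statistics.

    ``branch_W``/``branch_b`` hold the single shared branch (hidden layers
    then the embedding map); both timepoints pass through this one object.
    """

    config: LSNConfig
    branch_W: list[np.ndarray]
    branch_b: list[np.ndarray]
    gate_w: float
    gate_c: float
    head_W1: np.ndarray
    head_b1: np.ndarray
    head_W2: np.ndarray
    head_b2: np.ndarray
    ct_mean: np.ndarray
    ct_sd: np.ndarray
    score_mean: float
    score_sd: float
    age_mean: float
    age_sd: float
    class_labels: list[str] = field(default_factory=list)

    def flat(self) -> list[np.ndarray]:
        return (self.branch_W + self.branch_b
                + [np.array([self.gate_w]), np.array([self.gate_c]),
                   self.head_W1, self.head_b1, self.head_W2, self.head_b2])

    def n_parameters(self) -> int:
        return sum(p.size for p in self.flat())


def parameter_count(config: LSNConfig) -> int:
    """Closed-form parameter count for a given architecture."""
    R, W, E, H, C = (config.roi_count, config.branch_width,
                     config.embedding_dim, config.head_width, config.n_classes)
    L = config.branch_layers
    branch = (R * W + W) + (L - 1) * (W * W + W) + (W * E + E)
    gate = 2
    head = ((E + 3) * H + H) + (H * C + C)
    return branch + gate + head


def build_lsn(config: LSNConfig, class_labels: Optional[Sequence[str]] = None) -> LSNParameters:
    """Initialize parameters deterministically from ``config.seed``.

    He-style scaled Gaussian init for rectifier layers; the gate starts
    near identity (g ≈ 0.73 at apoe4 = 0) so early training is not starved
    of gradient through the embedding.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    dims = ([config.roi_count] + [config.branch_width] * config.branch_layers
            + [config.embedding_dim])
    branch_W, branch_b = [], []
    for d_in, d_out in zip(dims, dims[1:]):
        branch_W.append(rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out)))
        branch_b.append(np.zeros(d_out))
    head_in = config.embedding_dim + 3
    return LSNParameters(
        config=config,
        branch_W=branch_W,
        branch_b=branch_b,
        gate_w=0.0,
        gate_c=1.0,
        head_W1=rng.normal(0.0, np.sqrt(2.0 / head_in), size=(head_in, config.head_width)),
        head_b1=np.zeros(config.head_width),
        head_W2=rng.normal(0.0, np.sqrt(2.0 / config.head_width),
                           size=(config.head_width, config.n_classes)),
        head_b2=np.zeros(config.n_classes),
        ct_mean=np.zeros(config.roi_count),
        ct_sd=np.ones(config.roi_count),
        score_mean=0.0,
        score_sd=1.0,
        age_mean=0.0,
        age_sd=1.0,
        class_labels=list(class_labels) if class_labels else [],
    )


# ---------------------------------------------------------------------------
# Forward pass


def _branch_forward(params: LSNParameters, X: np.ndarray):
    """Shared branch: hidden rectifier layers, then the linear embedding map."""
    acts = [X]
    h = X
    n_hidden = params.config.branch_layers
    for l in range(n_hidden):
        h = np.maximum(h @ params.branch_W[l] + params.branch_b[l], 0.0)
        acts.append(h)
    e = h @ params.branch_W[n_hidden] + params.branch_b[n_hidden]
    acts.append(e)
    return e, acts


def _standardize_ct(params: LSNParameters, X: np.ndarray) -> np.ndarray:
    return (X - params.ct_mean) / params.ct_sd


def distance_embedding(params: LSNParameters, ct_t0: np.ndarray, ct_t1: np.ndarray) -> np.ndarray:
    """e = b(ct_t1) − b(ct_t0) under the single shared branch map b."""
    x0 = np.atleast_2d(np.asarray(ct_t0, dtype=float))
    x1 = np.atleast_2d(np.asarray(ct_t1, dtype=float))
    if x0.shape[1] != params.config.roi_count or x1.shape[1] != params.config.roi_count:
        raise LsnInputError(f"CT length must equal roi_count={params.config.roi_count}")
    e1, _ = _branch_forward(params, _standardize_ct(params, x1))
    e0, _ = _branch_forward(params, _standardize_ct(params, x0))
    out = e1 - e0
    return out[0] if np.asarray(ct_t0).ndim == 1 else out


def modulate(params: LSNParameters, embedding: np.ndarray, apoe4) -> np.ndarray:
    """Scale the embedding by the logistic gate g = σ(w·apoe4 + c)."""
    a = np.asarray(apoe4)
    if not np.all(np.isin(a, (0, 1, 2))):
        raise LsnInputError(f"apoe4 values must be in {{0,1,2}}, got {apoe4!r}")
    g = _sigmoid(params.gate_w * a.astype(float) + params.gate_c)
    emb = np.asarray(embedding, dtype=float)
    if emb.ndim == 1:
        return float(g) * emb
    return np.asarray(g)[:, None] * emb


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward_batch(params: LSNParameters, X0, X1, s0, s1, age, apoe4,
                   dropout_mask=None):
    """Full forward pass on standardized-at-entry raw inputs; returns caches.

    ``dropout_mask`` (training only) is an inverted-dropout mask applied to
    the modulated embedding; at inference it is None and no scaling occurs.
    """
    X0s = _standardize_ct(params, X0)
    X1s = _standardize_ct(params, X1)
    e1, acts1 = _branch_forward(params, X1s)
    e0, acts0 = _branch_forward(params, X0s)
    e = e1 - e0
    g = _sigmoid(params.gate_w * apoe4 + params.gate_c)
    m = g[:, None] * e
    if dropout_mask is not None:
        m = m * dropout_mask
    s0s = (s0 - params.score_mean) / params.score_sd
    s1s = (s1 - params.score_mean) / params.score_sd
    ages = (age - params.age_mean) / params.age_sd
    z = np.column_stack([m, s0s, s1s, ages])
    u_pre = z @ params.head_W1 + params.head_b1
    u = np.maximum(u_pre, 0.0)
    logits = u @ params.head_W2 + params.head_b2
    p = _softmax(logits)
    cache = dict(acts0=acts0, acts1=acts1, e=e, g=g, apoe4=apoe4, z=z, u=u, p=p,
                 dropout_mask=dropout_mask)
    return p, cache


def _stack_inputs(inputs: Sequence[PredictionInput], roi_count: int):
    for x in inputs:
        x.validate(roi_count)
    X0 = np.stack([np.asarray(x.ct_t0, dtype=float) for x in inputs])
    X1 = np.stack([np.asarray(x.ct_t1, dtype=float) for x in inputs])
    s0 = np.array([x.score_t0 for x in inputs], dtype=float)
    s1 = np.array([x.score_t1 for x in inputs], dtype=float)
    age = np.array([x.age for x in inputs], dtype=float)
    apoe4 = np.array([x.apoe4 for x in inputs], dtype=float)
    return X0, X1, s0, s1, age, apoe4


def predict_proba(params: LSNParameters, inputs: Sequence[PredictionInput]) -> np.ndarray:
    """Class-probability matrix (n_subjects, n_classes); rows sum to 1."""
    X0, X1, s0, s1, age, apoe4 = _stack_inputs(inputs, params.config.roi_count)
    p, _ = _forward_batch(params, X0, X1, s0, s1, age, apoe4)
    return p


def predict(params: LSNParameters, x: PredictionInput) -> np.ndarray:
    """Probability vector for a single subject."""
    return predict_proba(params, [x])[0]


# ---------------------------------------------------------------------------
# Backward pass and training


def _backward_batch(params: LSNParameters, cache, Y: np.ndarray):
    """Gradients of mean cross-entropy w.r.t. every parameter.

    The shared branch receives the upstream gradient +de through the
    follow-up activations and −de through the baseline activations; the two
    contributions accumulate into the one parameter set.
    """
    B = Y.shape[0]
    p, z, u = cache["p"], cache["z"], cache["u"]
    g, e, apoe4 = cache["g"], cache["e"], cache["apoe4"]
    E = params.config.embedding_dim

    dlogits = (p - Y) / B
    d_head_W2 = u.T @ dlogits
    d_head_b2 = dlogits.sum(axis=0)
    du = dlogits @ params.head_W2.T
    du = du * (u > 0)
    d_head_W1 = z.T @ du
    d_head_b1 = du.sum(axis=0)
    dz = du @ params.head_W1.T
    dm = dz[:, :E]
    if cache["dropout_mask"] is not None:
        dm = dm * cache["dropout_mask"]

    dg = (dm * e).sum(axis=1)
    de = dm * g[:, None]
    dgate_pre = dg * g * (1.0 - g)
    d_gate_w = float((dgate_pre * apoe4).sum())
    d_gate_c = float(dgate_pre.sum())

    n_layers = len(params.branch_W)
    dW = [np.zeros_like(W) for W in params.branch_W]
    db = [np.zeros_like(b) for b in params.branch_b]
    for acts, sign in ((cache["acts1"], 1.0), (cache["acts0"], -1.0)):
        grad = sign * de
        for l in range(n_layers - 1, -1, -1):
            a_in = acts[l]
            dW[l] += a_in.T @ grad
            db[l] += grad.sum(axis=0)
            if l > 0:
                grad = (grad @ params.branch_W[l].T) * (acts[l] > 0)
    return dW, db, d_gate_w, d_gate_c, d_head_W1, d_head_b1, d_head_W2, d_head_b2


class _Adam:
    """Adam with decoupled weight decay (applied to weight matrices only)."""

    def __init__(self, shapes, lr, decay_mask, weight_decay=0.0,
                 beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.wd = weight_decay
        self.decay_mask = decay_mask
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params_list, grads_list):
        self.t += 1
        for i, (p, gr) in enumerate(zip(params_list, grads_list)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * gr
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * gr * gr
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.wd and self.decay_mask[i]:
                p -= self.lr * self.wd * p


def _one_hot(y: np.ndarray, n_classes: int) -> np.ndarray:
    Y = np.zeros((len(y), n_classes))
    Y[np.arange(len(y)), y] = 1.0
    return Y


def _cross_entropy(p: np.ndarray, Y: np.ndarray) -> float:
    return float(-np.mean(np.sum(Y * np.log(np.clip(p, 1e-12, None)), axis=1)))


def fit_standardization(params: LSNParameters, inputs: Sequence[PredictionInput]) -> None:
    """Fit input statistics on training data only (stored in the model).

    CT statistics are pooled per ROI over both timepoints; score statistics
    over both scores. Zero spreads fall back to 1.
    """
    X0, X1, s0, s1, age, _ = _stack_inputs(inputs, params.config.roi_count)
    ct_all = np.vstack([X0, X1])
    params.ct_mean = ct_all.mean(axis=0)
    params.ct_sd = np.where(ct_all.std(axis=0) > 1e-12, ct_all.std(axis=0), 1.0)
    scores = np.concatenate([s0, s1])
    params.score_mean = float(scores.mean())
    params.score_sd = float(scores.std()) if scores.std() > 1e-12 else 1.0
    params.age_mean = float(age.mean())
    params.age_sd = float(age.std()) if age.std() > 1e-12 else 1.0


def train_lsn(
    inputs: Sequence[PredictionInput],
    labels: Sequence[int],
    config: LSNConfig,
    class_labels: Optional[Sequence[str]] = None,
    validation_index: Optional[np.ndarray] = None,
) -> tuple[LSNParameters, dict]:
    """Train by Adam with early stopping; deterministic given config.seed.

    ``labels`` are integer class indices in [0, n_classes). A stratified
    validation split of ``config.validation_fraction`` is drawn from the
    seed unless ``validation_index`` marks validation rows explicitly.
    Returns (parameters at the best validation loss, training history).
    """
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    params = build_lsn(config, class_labels=class_labels)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7919]))

    n = len(inputs)
    if validation_index is None:
        val_mask = np.zeros(n, dtype=bool)
        for c in np.unique(y):
            idx = np.flatnonzero(y == c)
            n_val = max(1, int(round(config.validation_fraction * len(idx))))
            val_mask[rng.choice(idx, size=n_val, replace=False)] = True
    else:
        val_mask = np.zeros(n, dtype=bool)
        val_mask[np.asarray(validation_index)] = True
    tr_idx = np.flatnonzero(~val_mask)
    va_idx = np.flatnonzero(val_mask)

    train_inputs = [inputs[i] for i in tr_idx]
    fit_standardization(params, train_inputs)
    X0, X1, s0, s1, age, apoe4 = _stack_inputs(inputs, config.roi_count)
    Y = _one_hot(y, config.n_classes)

    def slices(idx):
        return X0[idx], X1[idx], s0[idx], s1[idx], age[idx], apoe4[idx], Y[idx]

    flat_shapes = [p.shape for p in params.branch_W] + [p.shape for p in params.branch_b]
    flat_shapes += [(), (), params.head_W1.shape, params.head_b1.shape,
                    params.head_W2.shape, params.head_b2.shape]
    decay_mask = ([True] * len(params.branch_W) + [False] * len(params.branch_b)
                  + [False, False, True, False, True, False])
    opt = _Adam(flat_shapes, config.learning_rate, decay_mask, config.weight_decay)

    best_val = np.inf
    best_state = None
    patience = 0
    history = {"train_loss": [], "val_loss": []}

    def snapshot():
        return ([W.copy() for W in params.branch_W], [b.copy() for b in params.branch_b],
                params.gate_w, params.gate_c, params.head_W1.copy(), params.head_b1.copy(),
                params.head_W2.copy(), params.head_b2.copy())

    for epoch in range(config.max_epochs):
        order = rng.permutation(tr_idx)
        for start in range(0, len(order), config.batch_size):
            bidx = order[start:start + config.batch_size]
            bX0, bX1, bs0, bs1, bage, bap, bY = slices(bidx)
            mask = None
            if config.embedding_dropout > 0:
                keep = 1.0 - config.embedding_dropout
                mask = (rng.random((len(bidx), config.embedding_dim)) < keep) / keep
            p, cache = _forward_batch(params, bX0, bX1, bs0, bs1, bage, bap,
                                      dropout_mask=mask)
            dW, db, dgw, dgc, dH1, dB1, dH2, dB2 = _backward_batch(params, cache, bY)
            gw = np.array(params.gate_w)
            gc = np.array(params.gate_c)
            plist = params.branch_W + params.branch_b + [gw, gc, params.head_W1,
                                                         params.head_b1, params.head_W2, params.head_b2]
            glist = dW + db + [np.array(dgw), np.array(dgc), dH1, dB1, dH2, dB2]
            opt.step(plist, glist)
            params.gate_w = float(gw)
            params.gate_c = float(gc)

        tX0, tX1, ts0, ts1, tage, tap, tY = slices(tr_idx)
        p_tr, _ = _forward_batch(params, tX0, tX1, ts0, ts1, tage, tap)
        train_loss = _cross_entropy(p_tr, tY)
        vX0, vX1, vs0, vs1, vage, vap, vY = slices(va_idx)
        p_va, _ = _forward_batch(params, vX0, vX1, vs0, vs1, vage, vap)
        val_loss = _cross_entropy(p_va, vY)
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        if not np.isfinite(train_loss) or not np.isfinite(val_loss):
            raise ArithmeticError(
                f"non-finite loss at epoch {epoch} "
                f"(train={train_loss}, val={val_loss}); reduce the learning rate"
            )
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_state = snapshot()
            patience = 0
        else:
            patience += 1
            if patience >= config.early_stop_patience:
                break

    if best_state is not None:
        (params.branch_W, params.branch_b, params.gate_w, params.gate_c,
         params.head_W1, params.head_b1, params.head_W2, params.head_b2) = best_state
    history["best_val_loss"] = best_val
    history["epochs_run"] = len(history["train_loss"])
    return params, history


# ---------------------------------------------------------------------------
# Serialization: JSON header + base64 little-endian float64 blocks


def _enc(a: np.ndarray) -> dict:
    a = np.ascontiguousarray(a, dtype="<f8")
    return {"shape": list(a.shape), "data": base64.b64encode(a.tobytes()).decode("ascii")}


def _dec(d: dict) -> np.ndarray:
    return np.frombuffer(base64.b64decode(d["data"]), dtype="<f8").reshape(d["shape"]).copy()


def save_lsn(params: LSNParameters, path) -> None:
    doc = {
        "format": "cogtraj-lsn-v1",
        "config": asdict(params.config),
        "class_labels": params.class_labels,
        "gate_w": params.gate_w,
        "gate_c": params.gate_c,
        "score_mean": params.score_mean,
        "score_sd": params.score_sd,
        "age_mean": params.age_mean,
        "age_sd": params.age_sd,
        "branch_W": [_enc(W) for W in params.branch_W],
        "branch_b": [_enc(b) for b in params.branch_b],
        "head_W1": _enc(params.head_W1),
        "head_b1": _enc(params.head_b1),
        "head_W2": _enc(params.head_W2),
        "head_b2": _enc(params.head_b2),
        "ct_mean": _enc(params.ct_mean),
        "ct_sd": _enc(params.ct_sd),
    }
    with open(path, "w") as f:
        json.dump(doc, f, indent=1, sort_keys=True)


def load_lsn(path) -> LSNParameters:
    with open(path) as f:
        doc = json.load(f)
    if doc.get("format") != "cogtraj-lsn-v1":
        raise ValueError(f"not a cogtraj LSN model file: {path}")
    config = LSNConfig(**doc["config"])
    return LSNParameters(
        config=config,
        branch_W=[_dec(d) for d in doc["branch_W"]],
        branch_b=[_dec(d) for d in doc["branch_b"]],
        gate_w=doc["gate_w"],
        gate_c=doc["gate_c"],
        head_W1=_dec(doc["head_W1"]),
        head_b1=_dec(doc["head_b1"]),
        head_W2=_dec(doc["head_W2"]),
        head_b2=_dec(doc["head_b2"]),
        ct_mean=_dec(doc["ct_mean"]),
        ct_sd=_dec(doc["ct_sd"]),
        score_mean=doc["score_mean"],
        score_sd=doc["score_sd"],
        age_mean=doc["age_mean"],
        age_sd=doc["age_sd"],
        class_labels=doc["class_labels"],
    )
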