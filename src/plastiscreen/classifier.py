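"""Per-polymer enzyme classifiers over fixed-length embeddings.

Two prediction modes mirror the screening tool's trade-off:

* ``default`` — gradient-boosted trees (XGBoost), precision-oriented;
* ``sensitive`` — a single-hidden-layer neural network with dropout and
  early stopping, recall-oriented.

Both modes train one independent binary probabilistic head per polymer
(one-vs-rest, since annotations are multi-label), weight classes inversely to
their frequency, and pick hyperparameters by grid search on an internal
validation split.  Everything is deterministic given the seed.

The sensitive-mode network is implemented directly on numpy (binary
cross-entropy loss, Adam optimizer, minibatch size 32, inverted dropout),
keeping training reproducible bit-for-bit across runs.
"""

from __future__ import annotations

import base64
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import xgboost as xgb

__all__ = ["TrainConfig", "ClassifierModel", "train", "predict_scores", "classify",
           "save_model", "load_model"]

ARCHIVE_VERSION = 1


@dataclass
class TrainConfig:
    mode: str = "default"  # "default" | "sensitive"
    hidden_units: int = 128
    dropout_rate: float = 0.3
    max_epochs: int = 200
    patience: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-3
    validation_fraction: float = 0.1
    n_estimators: int = 100
    # grid-search candidate lists
    grid_max_depth: tuple[int, ...] = (3, 5, 7)
    grid_learning_rate: tuple[float, ...] = (0.05, 0.1, 0.3)
    grid_hidden_units: tuple[int, ...] = (64, 128)
    grid_dropout: tuple[float, ...] = (0.2, 0.3)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be < max_epochs")
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0, 1)")


# ---------------------------------------------------------------------------
# sensitive mode: single-hidden-layer network with dropout + early stopping
# ---------------------------------------------------------------------------


class _MLPHead:
    """Binary classifier: sigmoid(ReLU(x W1 + b1) W2 + b2)."""

    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / dim)
        self.W1 = rng.normal(0.0, scale, size=(dim, hidden))
        self.b1 = np.zeros(hidden)
        self.W2 = rng.normal(0.0, np.sqrt(2.0 / hidden), size=hidden)
        self.b2 = 0.0

    def params(self):
        return [self.W1, self.b1, self.W2, np.array([self.b2])]

    def set_params(self, params):
        self.W1, self.b1, self.W2 = params[0].copy(), params[1].copy(), params[2].copy()
        self.b2 = float(params[3][0])

    def forward(self, X: np.ndarray) -> np.ndarray:
        h = np.maximum(X @ self.W1 + self.b1, 0.0)
        z = h @ self.W2 + self.b2
        return 1.0 / (1.0 + np.exp(-z))


def _weighted_bce(p: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(w * (y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))))


def _train_mlp(
    X: np.ndarray, y: np.ndarray, Xv: np.ndarray, yv: np.ndarray,
    hidden: int, dropout: float, config: TrainConfig, seed: int,
) -> tuple[_MLPHead, int]:
    rng = np.random.default_rng(seed)
    head = _MLPHead(X.shape[1], hidden, rng)
    # class weights from the training label distribution, applied to both sets
    n, n_pos = len(y), int(y.sum())
    w_pos = n / (2.0 * max(n_pos, 1))
    w_neg = n / (2.0 * max(n - n_pos, 1))
    w_train = np.where(y == 1, w_pos, w_neg)
    wv = np.where(yv == 1, w_pos, w_neg)
    # Adam state
    params = head.params()
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps, lr = 0.9, 0.999, 1e-8, config.learning_rate
    t = 0
    best_loss, best_params, wait, stopped_at = np.inf, None, 0, config.max_epochs
    n = X.shape[0]
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb, wb = X[idx], y[idx], w_train[idx]
            z1 = xb @ head.W1 + head.b1
            h = np.maximum(z1, 0.0)
            if dropout > 0:
                mask = (rng.random(h.shape) >= dropout) / (1.0 - dropout)
                hd = h * mask
            else:
                mask = None
                hd = h
            z2 = hd @ head.W2 + head.b2
            p = 1.0 / (1.0 + np.exp(-z2))
            dz2 = wb * (p - yb) / len(idx)
            gW2 = hd.T @ dz2
            gb2 = dz2.sum()
            dh = np.outer(dz2, head.W2)
            if mask is not None:
                dh = dh * mask
            dz1 = dh * (z1 > 0)
            gW1 = xb.T @ dz1
            gb1 = dz1.sum(axis=0)
            grads = [gW1, gb1, gW2, np.array([gb2])]
            t += 1
            params = head.params()
            for i, (pp, g) in enumerate(zip(params, grads)):
                m[i] = beta1 * m[i] + (1 - beta1) * g
                v[i] = beta2 * v[i] + (1 - beta2) * g * g
                mh = m[i] / (1 - beta1**t)
                vh = v[i] / (1 - beta2**t)
                pp -= lr * mh / (np.sqrt(vh) + eps)
            head.set_params(params)
        val_loss = _weighted_bce(head.forward(Xv), yv, wv)
        if val_loss < best_loss - 1e-6:
            best_loss, best_params, wait = val_loss, [p.copy() for p in head.params()], 0
        else:
            wait += 1
            if wait >= config.patience:
                stopped_at = epoch + 1
                break
    if best_params is not None:
        head.set_params(best_params)
    return head, stopped_at


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------


@dataclass
class ClassifierModel:
    mode: str
    polymers: list[str]
    embedder_name: str
    dim: int
    heads: dict = field(default_factory=dict)  # polymer -> fitted head
    hyperparams: dict = field(default_factory=dict)  # polymer -> chosen grid point
    seed: int = 0


def _f1_binary(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = int(((y_pred == 1) & (y_true == 1)).sum())
    fp = int(((y_pred == 1) & (y_true == 0)).sum())
    fn = int(((y_pred == 0) & (y_true == 1)).sum())
    if tp == 0:
        return 0.0
    p = tp / (tp + fp)
    r = tp / (tp + fn)
    return 2 * p * r / (p + r)


def _split_validation(n: int, fraction: float, y: np.ndarray, rng: np.random.Generator):
    """Index split keeping at least one positive and one negative in train."""
    n_val = max(1, int(round(fraction * n)))
    for _ in range(100):
        order = rng.permutation(n)
        val, tr = order[:n_val], order[n_val:]
        if 0 < y[tr].sum() < len(tr):
            return tr, val
    raise ValueError("could not form a validation split with both classes in train")


def _fit_xgb(X, y, depth, lr, n_estimators, seed) -> xgb.XGBClassifier:
    n_pos = int(y.sum())
    spw = (len(y) - n_pos) / n_pos
    clf = xgb.XGBClassifier(
        max_depth=depth,
        learning_rate=lr,
        n_estimators=n_estimators,
        scale_pos_weight=spw,
        random_state=seed,
        n_jobs=1,
        tree_method="hist",
        eval_metric="logloss",
        verbosity=0,
    )
    clf.fit(X, y)
    return clf


def train(
    mode: str,
    X: np.ndarray,
    Y: np.ndarray,
    config: Optional[TrainConfig] = None,
    polymers: Optional[Sequence[str]] = None,
    embedder_name: str = "onehot-physchem-v1",
) -> ClassifierModel:
    """Fit one binary head per polymer with grid-searched hyperparameters.

    Hyperparameters are chosen by validation F1 on an internal split.  The
    default mode then refits on all rows; the sensitive mode keeps the
    validation rows out for early stopping.
    """
    config = config or TrainConfig(mode=mode)
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=int))
    if Y.shape[0] != X.shape[0]:
        Y = Y.T
    n, k = Y.shape
    if n < 20:
        raise ValueError("training requires at least 20 examples")
    if mode not in ("default", "sensitive"):
        raise ValueError(f"unknown mode {mode!r}")
    polymers = list(polymers) if polymers is not None else [f"polymer_{i}" for i in range(k)]
    model = ClassifierModel(
        mode=mode, polymers=polymers, embedder_name=embedder_name,
        dim=X.shape[1], seed=config.seed,
    )
    for j, polymer in enumerate(polymers):
        y = Y[:, j]
        if y.sum() == 0:
            raise ValueError(f"polymer {polymer!r} has no positive training examples")
        if y.sum() == n:
            raise ValueError(f"polymer {polymer!r} has no negative training examples")
        rng = np.random.default_rng(config.seed + 1000 * j)
        tr, val = _split_validation(n, config.validation_fraction, y, rng)
        if mode == "default":
            best = (-1.0, None)
            for depth in config.grid_max_depth:
                for lr in config.grid_learning_rate:
                    clf = _fit_xgb(X[tr], y[tr], depth, lr, config.n_estimators, config.seed)
                    f1 = _f1_binary(y[val], (clf.predict_proba(X[val])[:, 1] > 0.5).astype(int))
                    if f1 > best[0]:
                        best = (f1, (depth, lr))
            depth, lr = best[1]
            model.hyperparams[polymer] = {"max_depth": depth, "learning_rate": lr}
            model.heads[polymer] = _fit_xgb(X, y, depth, lr, config.n_estimators, config.seed)
        else:
            best = (-1.0, None)
            for hidden in config.grid_hidden_units:
                for dropout in config.grid_dropout:
                    head, _ = _train_mlp(
                        X[tr], y[tr], X[val], y[val], hidden, dropout, config,
                        seed=config.seed + 7 * hidden + int(100 * dropout),
                    )
                    f1 = _f1_binary(y[val], (head.forward(X[val]) > 0.5).astype(int))
                    if f1 > best[0]:
                        best = (f1, (hidden, dropout))
            hidden, dropout = best[1]
            model.hyperparams[polymer] = {"hidden_units": hidden, "dropout_rate": dropout}
            head, stopped = _train_mlp(
                X[tr], y[tr], X[val], y[val], hidden, dropout, config,
                seed=config.seed + 7 * hidden + int(100 * dropout),
            )
            model.hyperparams[polymer]["stopped_at_epoch"] = stopped
            model.heads[polymer] = head
    return model


def predict_scores(model: ClassifierModel, X: np.ndarray) -> np.ndarray:
    """Per-polymer probabilities, shape (n, k), row order preserved."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.dim:
        raise ValueError(f"embedding dim {X.shape} does not match model dim {model.dim}")
    cols = []
    for polymer in model.polymers:
        head = model.heads[polymer]
        if isinstance(head, _MLPHead):
            cols.append(head.forward(X))
        else:
            cols.append(head.predict_proba(X)[:, 1])
    return np.column_stack(cols)


def classify(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Boolean calls at a strictly-greater threshold.

    0.5 is the benchmarking cut; 0.7 marks high-confidence reporting.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    return np.asarray(scores) > threshold


# ---------------------------------------------------------------------------
# persistence: versioned single-file JSON archive
# ---------------------------------------------------------------------------


def save_model(model: ClassifierModel, path: str) -> None:
    doc = {
        "format": "plastiscreen-classifier",
        "version": ARCHIVE_VERSION,
        "mode": model.mode,
        "polymers": model.polymers,
        "embedder_name": model.embedder_name,
        "dim": model.dim,
        "seed": model.seed,
        "hyperparams": model.hyperparams,
        "heads": {},
    }
    for polymer, head in model.heads.items():
        if isinstance(head, _MLPHead):
            doc["heads"][polymer] = {
                "kind": "mlp",
                "W1": head.W1.tolist(), "b1": head.b1.tolist(),
                "W2": head.W2.tolist(), "b2": head.b2,
            }
        else:
            raw = head.get_booster().save_raw("json")
            doc["heads"][polymer] = {
                "kind": "xgb",
                "booster": base64.b64encode(bytes(raw)).decode("ascii"),
            }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path: str, expected_embedder: Optional[str] = None) -> ClassifierModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "plastiscreen-classifier":
        raise ValueError(f"{path}: not a classifier archive")
    if expected_embedder is not None and doc["embedder_name"] != expected_embedder:
        raise ValueError(
            f"model was trained on embedder {doc['embedder_name']!r}, "
            f"refusing to score {expected_embedder!r} embeddings"
        )
    model = ClassifierModel(
        mode=doc["mode"], polymers=doc["polymers"], embedder_name=doc["embedder_name"],
        dim=doc["dim"], seed=doc["seed"], hyperparams=doc["hyperparams"],
    )
    for polymer, spec in doc["heads"].items():
        if spec["kind"] == "mlp":
            head = _MLPHead.__new__(_MLPHead)
            head.W1 = np.array(spec["W1"])
            head.b1 = np.array(spec["b1"])
            head.W2 = np.array(spec["W2"])
            head.b2 = float(spec["b2"])
            model.heads[polymer] = head
        else:
            clf = xgb.XGBClassifier()
            clf.load_model(bytearray(base64.b64decode(spec["booster"])))
            model.heads[polymer] = clf
    return model
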