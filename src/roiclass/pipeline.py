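"""Classification pipeline building blocks.

A trained pipeline is a per-feature min-max scaler followed by one of two
binary classifiers: a linear soft-margin SVC, or a small fully connected
network (input -> hidden1 with l2 penalty and dropout -> hidden2 -> 2
softmax outputs) trained with Adam on full-batch cross-entropy. The
network uses linear activations by default; ``relu`` is available as an
extension.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.svm import SVC as _SklearnSVC

from .cohort import ROICohort


class PipelineError(ValueError):
    pass


# ---------------------------------------------------------------------------
# imbalance correction


def balance_indices(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Undersample the majority class (without replacement) to minority size.

    Returns row indices in ascending order; minority rows are all kept.
    """
    labels = np.asarray(labels)
    idx0 = np.flatnonzero(labels == 0)
    idx1 = np.flatnonzero(labels == 1)
    if idx0.size == 0 or idx1.size == 0:
        raise PipelineError("both classes must be present to balance")
    if idx0.size == idx1.size:
        return np.arange(labels.size)
    minority, majority = (idx0, idx1) if idx0.size < idx1.size else (idx1, idx0)
    kept = rng.choice(majority, size=minority.size, replace=False)
    return np.sort(np.concatenate([minority, kept]))


def balance_cohort(
    cohort: ROICohort, labels: np.ndarray, seed: int | np.random.Generator
) -> tuple[ROICohort, np.ndarray]:
    """Cohort-level undersampling wrapper around :func:`balance_indices`."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = balance_indices(labels, rng)
    return cohort.take(idx), np.asarray(labels)[idx]


# ---------------------------------------------------------------------------
# ROI variable scaling


@dataclass(frozen=True)
class ScalerParams:
    minimum: np.ndarray
    maximum: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.maximum < self.minimum):
            raise PipelineError("per-feature maximum must be >= minimum")


def fit_scaler(X_fit: np.ndarray) -> ScalerParams:
    X_fit = np.asarray(X_fit, dtype=float)
    if X_fit.size == 0:
        raise PipelineError("cannot fit scaler on an empty matrix")
    return ScalerParams(minimum=X_fit.min(axis=0), maximum=X_fit.max(axis=0))


def apply_scaler(params: ScalerParams, X: np.ndarray) -> np.ndarray:
    """x' = (x - min) / (max - min); constant features map to 0; no clipping."""
    X = np.asarray(X, dtype=float)
    span = params.maximum - params.minimum
    out = np.zeros_like(X)
    ok = span > 0
    out[:, ok] = (X[:, ok] - params.minimum[ok]) / span[ok]
    return out


def inverse_scaler(params: ScalerParams, Xs: np.ndarray) -> np.ndarray:
    span = params.maximum - params.minimum
    return np.asarray(Xs) * span + params.minimum


# ---------------------------------------------------------------------------
# support vector classifier


@dataclass(frozen=True)
class SVCConfig:
    C: float = 1.0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise PipelineError("C must be > 0")


def svc_grid(start: float = 0.1, stop: float = 2.0, step: float = 0.05) -> list[float]:
    """Default regularization grid: 0.1 to 2.0 in 0.05 increments (39 values)."""
    n = int(round((stop - start) / step)) + 1
    return [round(start + i * step, 10) for i in range(n)]


class SVCModel:
    """Linear soft-margin SVC; ``decision_scores`` is the signed distance."""

    kind = "svc"

    def __init__(self, estimator: _SklearnSVC, config: SVCConfig):
        self._est = estimator
        self.config = config

    @property
    def coef(self) -> np.ndarray:
        return self._est.coef_.ravel()

    @property
    def intercept(self) -> float:
        return float(self._est.intercept_[0])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._est.predict(np.asarray(X, dtype=float))

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return self._est.decision_function(np.asarray(X, dtype=float))


def train_svc(X: np.ndarray, y: np.ndarray, config: SVCConfig) -> "SVCModel":
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise PipelineError("training labels contain a single class")
    est = _SklearnSVC(kernel="linear", C=config.C)
    est.fit(np.asarray(X, dtype=float), y)
    return SVCModel(est, config)


# ---------------------------------------------------------------------------
# dense-network classifier


@dataclass(frozen=True)
class DLCConfig:
    learning_rate: float = 0.005
    epochs: int = 300
    hidden1: int = 20
    hidden2: int = 5
    l2_penalty: float = 0.1
    dropout_rate: float = 0.2
    activation: str = "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden1 < 1 or self.hidden2 < 1:
            raise PipelineError("hidden layer sizes must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise PipelineError("dropout rate must be in [0, 1)")
        if self.learning_rate <= 0 or self.epochs < 1:
            raise PipelineError("learning rate and epochs must be positive")
        if self.activation not in ("linear", "relu"):
            raise PipelineError("activation must be 'linear' or 'relu'")


class DLCModel:
    """Two-hidden-layer dense net with a 2-node softmax output.

    Dropout and the l2 penalty act on hidden layer 1 during training only;
    inference is deterministic. The output layer is zero-initialized, which
    makes label-swap symmetry exact for a fixed seed.
    """

    kind = "dlc"

    def __init__(self, weights: dict[str, np.ndarray], config: DLCConfig):
        self.W1 = weights["W1"]
        self.b1 = weights["b1"]
        self.W2 = weights["W2"]
        self.b2 = weights["b2"]
        self.W3 = weights["W3"]
        self.b3 = weights["b3"]
        self.config = config

    def _act(self, h: np.ndarray) -> np.ndarray:
        return np.maximum(h, 0.0) if self.config.activation == "relu" else h

    def logits(self, X: np.ndarray) -> np.ndarray:
        h1 = self._act(np.asarray(X, dtype=float) @ self.W1 + self.b1)
        h2 = self._act(h1 @ self.W2 + self.b2)
        return h2 @ self.W3 + self.b3

    def class_probabilities(self, X: np.ndarray) -> np.ndarray:
        return _softmax(self.logits(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.logits(X), axis=1)

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Probability of class 1, used for AUC ranking."""
        return self.class_probabilities(X)[:, 1]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def train_dlc(X: np.ndarray, y: np.ndarray, config: DLCConfig) -> DLCModel:
    """Full-batch Adam on softmax cross-entropy; reproducible from the seed."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise PipelineError("training labels contain a single class")
    n, n_in = X.shape
    rng = np.random.default_rng(config.seed)
    relu = config.activation == "relu"

    W1 = rng.standard_normal((n_in, config.hidden1)) / np.sqrt(n_in)
    b1 = np.zeros(config.hidden1)
    W2 = rng.standard_normal((config.hidden1, config.hidden2)) / np.sqrt(config.hidden1)
    b2 = np.zeros(config.hidden2)
    W3 = np.zeros((config.hidden2, 2))  # zero init: exact label-swap symmetry
    b3 = np.zeros(2)

    Y = np.zeros((n, 2))
    Y[np.arange(n), y] = 1.0

    params = [W1, b1, W2, b2, W3, b3]
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    keep = 1.0 - config.dropout_rate

    for t in range(1, config.epochs + 1):
        a1 = X @ W1 + b1
        h1 = np.maximum(a1, 0.0) if relu else a1
        if config.dropout_rate > 0:
            mask = (rng.random(h1.shape) < keep) / keep  # inverted dropout
            h1d = h1 * mask
        else:
            mask = None
            h1d = h1
        a2 = h1d @ W2 + b2
        h2 = np.maximum(a2, 0.0) if relu else a2
        logits = h2 @ W3 + b3
        p = _softmax(logits)

        # cross-entropy gradient, averaged over the batch
        g_logits = (p - Y) / n
        gW3 = h2.T @ g_logits
        gb3 = g_logits.sum(axis=0)
        g_h2 = g_logits @ W3.T
        if relu:
            g_h2 = g_h2 * (a2 > 0)
        gW2 = h1d.T @ g_h2
        gb2 = g_h2.sum(axis=0)
        g_h1 = g_h2 @ W2.T
        if mask is not None:
            g_h1 = g_h1 * mask
        if relu:
            g_h1 = g_h1 * (a1 > 0)
        gW1 = X.T @ g_h1 + 2.0 * config.l2_penalty * W1
        gb1 = g_h1.sum(axis=0)

        grads = [gW1, gb1, gW2, gb2, gW3, gb3]
        for k, (pk, gk) in enumerate(zip(params, grads)):
            m[k] = beta1 * m[k] + (1 - beta1) * gk
            v[k] = beta2 * v[k] + (1 - beta2) * gk * gk
            m_hat = m[k] / (1 - beta1**t)
            v_hat = v[k] / (1 - beta2**t)
            pk -= config.learning_rate * m_hat / (np.sqrt(v_hat) + eps)

    weights = {"W1": W1, "b1": b1, "W2": W2, "b2": b2, "W3": W3, "b3": b3}
    return DLCModel(weights, config)


# ---------------------------------------------------------------------------
# the assembled pipeline


@dataclass
class PipelineModel:
    """Fitted scaler + classifier + the hyperparameters that produced it."""

    scaler: ScalerParams
    classifier: SVCModel | DLCModel
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_scaler = self.scaler.minimum.size
        n_clf = (
            self.classifier.coef.size
            if self.classifier.kind == "svc"
            else self.classifier.W1.shape[0]
        )
        if n_scaler != n_clf:
            raise PipelineError("scaler feature count must equal classifier input size")

    @property
    def kind(self) -> str:
        return self.classifier.kind

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classifier.predict(apply_scaler(self.scaler, X))

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return self.classifier.decision_scores(apply_scaler(self.scaler, X))

    def to_json(self, path: str | Path) -> None:
        payload: dict = {
            "kind": self.kind,
            "hyperparams": self.hyperparams,
            "scaler": {
                "minimum": self.scaler.minimum.tolist(),
                "maximum": self.scaler.maximum.tolist(),
            },
        }
        if self.kind == "svc":
            payload["svc"] = {
                "coef": self.classifier.coef.tolist(),
                "intercept": self.classifier.intercept,
                "config": asdict(self.classifier.config),
            }
        else:
            payload["dlc"] = {
                name: getattr(self.classifier, name).tolist()
                for name in ("W1", "b1", "W2", "b2", "W3", "b3")
            }
            payload["dlc"]["config"] = asdict(self.classifier.config)
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineModel":
        payload = json.loads(Path(path).read_text())
        scaler = ScalerParams(
            minimum=np.asarray(payload["scaler"]["minimum"]),
            maximum=np.asarray(payload["scaler"]["maximum"]),
        )
        if payload["kind"] == "svc":
            spec = payload["svc"]
            clf = _LoadedSVC(
                np.asarray(spec["coef"]), float(spec["intercept"]), SVCConfig(**spec["config"])
            )
        else:
            spec = payload["dlc"]
            config = DLCConfig(**spec.pop("config"))
            clf = DLCModel({k: np.asarray(v) for k, v in spec.items()}, config)
        return cls(scaler=scaler, classifier=clf, hyperparams=payload.get("hyperparams", {}))


class _LoadedSVC:
    """Deserialized linear SVC: weight vector + bias only."""

    kind = "svc"

    def __init__(self, coef: np.ndarray, intercept: float, config: SVCConfig):
        self.coef = coef
        self.intercept = intercept
        self.config = config

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_scores(X) > 0).astype(int)


def train_pipeline(
    X_fit: np.ndarray,
    y_fit: np.ndarray,
    kind: str,
    hyperparams: dict,
) -> PipelineModel:
    """Fit scaler on ``X_fit`` then the classifier of ``kind`` on scaled data."""
    scaler = fit_scaler(X_fit)
    Xs = apply_scaler(scaler, X_fit)
    if kind == "svc":
        clf: SVCModel | DLCModel = train_svc(Xs, y_fit, SVCConfig(**hyperparams))
    elif kind == "dlc":
        clf = train_dlc(Xs, y_fit, DLCConfig(**hyperparams))
    else:
        raise PipelineError(f"unknown model kind {kind!r}")
    return PipelineModel(scaler=scaler, classifier=clf, hyperparams=dict(hyperparams))
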