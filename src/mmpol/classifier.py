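"""Single-hidden-layer MLP pixel classifier.

The model is deliberately minimal, matching the study design: one hidden
layer of 64 ReLU units, a single logistic output giving the probability of
the abnormal class, binary cross-entropy loss, Adam with learning rate
1e-5, ten epochs of shuffled mini-batches, no regularization and no early
stopping.  It is implemented directly in numpy so training is bit-for-bit
reproducible under a fixed seed and the learned weights serialize to a
portable JSON container.

:class:`PixelMLP` follows the scikit-learn estimator protocol (``fit`` /
``predict_proba`` / ``get_params``), so it composes with sklearn model
selection; module-level :func:`train` / :func:`predict_proba` /
:func:`probability_map` are thin wrappers used by the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from mmpol.features import M00_EPSILON, feature_columns
from mmpol.reconstruct import MuellerImage

__all__ = [
    "TrainConfig",
    "PixelMLP",
    "train",
    "predict_proba",
    "probability_map",
    "save_model",
    "load_model",
]

#: value written into probability maps where no prediction exists
NO_DATA = np.nan


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (defaults are the study settings)."""

    hidden_units: int = 64
    learning_rate: float = 1e-5
    epochs: int = 10
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def _sigmoid(z: NDArray) -> NDArray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class PixelMLP(BaseEstimator, ClassifierMixin):
    """One-hidden-layer ReLU perceptron with a logistic output.

    Parameters mirror :class:`TrainConfig`.  Fitted attributes:

    ``coefs_`` : list of weight matrices [(d, h), (h, 1)]
    ``intercepts_`` : list of bias vectors [(h,), (1,)]
    ``loss_curve_`` : mean training cross-entropy per epoch
    ``classes_`` : ndarray [0, 1] (1 = abnormal, the positive class)
    """

    def __init__(
        self,
        hidden_units: int = 64,
        learning_rate: float = 1e-5,
        epochs: int = 10,
        batch_size: int = 32,
        beta1: float = 0.9,
        beta2: float = 0.999,
        adam_epsilon: float = 1e-8,
        random_state: int = 0,
    ):
        self.hidden_units = hidden_units
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.beta1 = beta1
        self.beta2 = beta2
        self.adam_epsilon = adam_epsilon
        self.random_state = random_state

    # -- training -----------------------------------------------------------

    def fit(self, X, y) -> "PixelMLP":
        X, y = check_X_y(X, y, dtype=np.float64)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training data must contain both classes")
        if not np.array_equal(classes, [0, 1]):
            raise ValueError(f"labels must be binary 0/1, got {classes}")
        n, d = X.shape
        h = self.hidden_units
        rng = np.random.default_rng(self.random_state)

        # Glorot-uniform hidden layer (seed-controlled); the output head
        # starts at zero so the initial logit is 0 (probability 0.5) and
        # the score direction is learned, not inherited from random init
        lim1 = np.sqrt(6.0 / (d + h))
        w1 = rng.uniform(-lim1, lim1, size=(d, h))
        b1 = np.zeros(h)
        w2 = np.zeros((h, 1))
        b2 = np.zeros(1)

        params = [w1, b1, w2, b2]
        m_t = [np.zeros_like(p) for p in params]
        v_t = [np.zeros_like(p) for p in params]
        step = 0
        losses = []
        batch = min(self.batch_size, n)
        for _epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch):
                idx = order[start : start + batch]
                xb, yb = X[idx], y[idx]
                hidden_pre = xb @ w1 + b1
                hidden = np.maximum(hidden_pre, 0.0)
                logits = (hidden @ w2 + b2).ravel()
                p = _sigmoid(logits)
                # BCE via logits, numerically safe
                loss = np.mean(
                    np.maximum(logits, 0.0) - logits * yb + np.log1p(np.exp(-np.abs(logits)))
                )
                epoch_loss += loss * len(idx)

                dz = (p - yb)[:, None] / len(idx)  # (b, 1)
                gw2 = hidden.T @ dz
                gb2 = dz.sum(axis=0)
                dh = (dz @ w2.T) * (hidden_pre > 0.0)
                gw1 = xb.T @ dh
                gb1 = dh.sum(axis=0)

                step += 1
                grads = [gw1, gb1, gw2, gb2]
                for p_i, g_i, m_i, v_i in zip(params, grads, m_t, v_t):
                    m_i *= self.beta1
                    m_i += (1 - self.beta1) * g_i
                    v_i *= self.beta2
                    v_i += (1 - self.beta2) * g_i * g_i
                    m_hat = m_i / (1 - self.beta1**step)
                    v_hat = v_i / (1 - self.beta2**step)
                    p_i -= self.learning_rate * m_hat / (np.sqrt(v_hat) + self.adam_epsilon)
            losses.append(epoch_loss / n)

        self.coefs_ = [w1, w2]
        self.intercepts_ = [b1, b2]
        self.loss_curve_ = losses
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = d
        return self

    # -- inference ----------------------------------------------------------

    def decision_function(self, X) -> NDArray[np.float64]:
        check_is_fitted(self, "coefs_")
        X = check_array(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model expects {self.n_features_in_}"
            )
        hidden = np.maximum(X @ self.coefs_[0] + self.intercepts_[0], 0.0)
        return (hidden @ self.coefs_[1] + self.intercepts_[1]).ravel()

    def predict_proba(self, X) -> NDArray[np.float64]:
        p1 = _sigmoid(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> NDArray[np.int_]:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


# ---------------------------------------------------------------------------
# pipeline-facing wrappers


def _split_table(table: pd.DataFrame) -> tuple[NDArray, NDArray]:
    feat_cols = [c for c in table.columns if c.startswith("f")]
    X = table[feat_cols].to_numpy(dtype=float)
    y = table["label"].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("feature table contains non-finite values")
    return X, y


def train(table: pd.DataFrame, config: TrainConfig | None = None) -> PixelMLP:
    """Fit a :class:`PixelMLP` on a labeled feature table."""
    config = config or TrainConfig()
    if len(table) == 0:
        raise ValueError("feature table is empty")
    X, y = _split_table(table)
    model = PixelMLP(
        hidden_units=config.hidden_units,
        learning_rate=config.learning_rate,
        epochs=config.epochs,
        batch_size=config.batch_size,
        random_state=config.seed,
    )
    return model.fit(X, y)


def predict_proba(model: PixelMLP, features: NDArray) -> NDArray[np.float64]:
    """Abnormal-class probability per row, in [0, 1]."""
    return model.predict_proba(features)[:, 1]


def probability_map(
    model: PixelMLP, image: MuellerImage, mode: str = "pol", eps: float = M00_EPSILON
) -> NDArray[np.float64]:
    """H x W abnormality-probability image; invalid pixels carry NaN."""
    mats = image.matrices
    h, w = mats.shape[:2]
    wl_order = np.argsort(image.wavelengths)
    m00 = mats[:, :, :, 0, 0]
    valid = image.valid_mask & (m00 > eps).all(axis=2) & np.isfinite(mats).all(axis=(2, 3, 4))
    rows, cols = np.nonzero(valid)
    out = np.full((h, w), NO_DATA)
    if len(rows) == 0:
        return out
    sel = mats[rows, cols][:, wl_order]
    if mode == "pol":
        normed = sel / sel[:, :, 0:1, 0:1]
        feats = normed.reshape(len(rows), -1, 16)[:, :, 1:].reshape(len(rows), -1)
    elif mode == "nopol":
        feats = sel[:, :, 0, 0]
    else:
        raise ValueError(f"mode must be 'pol' or 'nopol', got {mode!r}")
    if feats.shape[1] != model.n_features_in_:
        raise ValueError(
            f"mode {mode!r} produces {feats.shape[1]} features but the model "
            f"expects {model.n_features_in_}"
        )
    out[rows, cols] = predict_proba(model, feats)
    return out


# ---------------------------------------------------------------------------
# persistence


def save_model(model: PixelMLP, path: str | Path) -> None:
    """Serialize a fitted model to a portable JSON container."""
    check_is_fitted(model, "coefs_")
    payload = {
        "format": "mmpol-pixelmlp-v1",
        "params": model.get_params(),
        "coefs": [c.tolist() for c in model.coefs_],
        "intercepts": [b.tolist() for b in model.intercepts_],
        "loss_curve": list(model.loss_curve_),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> PixelMLP:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "mmpol-pixelmlp-v1":
        raise ValueError("unrecognized model container")
    model = PixelMLP(**payload["params"])
    model.coefs_ = [np.asarray(c, dtype=float) for c in payload["coefs"]]
    model.intercepts_ = [np.asarray(b, dtype=float) for b in payload["intercepts"]]
    model.loss_curve_ = payload["loss_curve"]
    model.classes_ = np.array([0, 1])
    model.n_features_in_ = model.coefs_[0].shape[0]
    return model
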