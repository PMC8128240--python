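"""Five-layer multi-layer perceptron for binary expression classification.

Architecture: input dense (ReLU, L2 kernel penalty) -> dropout -> hidden
dense (ReLU, L2) -> dropout -> output (sigmoid, or two-unit softmax in
``output='softmax'`` mode).  Trained with cross-entropy loss and the AdaMax
optimizer for a fixed number of epochs, with no early stopping or
validation-driven callbacks.  Dropout is inverted dropout, active only
during training; with a default rate above 0.5 the majority of units are
silenced at every training step, which forces redundant representations of
the class signal across many genes.

Implemented directly on numpy so the forward/backward pass and optimizer
semantics are explicit and exactly reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = ["DNNConfig", "MLPBinaryClassifier"]


@dataclass(frozen=True)
class DNNConfig:
    """Hyperparameters of the MLP.

    Defaults are desk-scale choices: width 64, dropout 0.6 (more than half
    the units dropped, as intended by the architecture), L2 weight penalty
    5e-4, 60 epochs of batch-32 AdaMax at learning rate 2e-3.
    """

    hidden_units: int = 64
    dropout_rate: float = 0.6
    l2_lambda: float = 5e-4
    epochs: int = 60
    batch_size: int = 32
    learning_rate: float = 2e-3
    output: str = "sigmoid"  # or "softmax" (two-unit variant)
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in (0, 1)")
        if min(self.hidden_units, self.epochs, self.batch_size) < 1:
            raise ValueError("counts must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be >= 0")
        if self.output not in ("sigmoid", "softmax"):
            raise ValueError("output must be 'sigmoid' or 'softmax'")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class _AdaMax:
    """AdaMax: Adam variant with the infinity norm for the second moment."""

    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.u = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads) -> None:
        self.t += 1
        bias = 1.0 - self.b1**self.t
        for p, g, m, u in zip(params, grads, self.m, self.u):
            m *= self.b1
            m += (1.0 - self.b1) * g
            np.maximum(self.b2 * u, np.abs(g), out=u)
            p -= (self.lr / bias) * m / (u + self.eps)


class MLPBinaryClassifier:
    """Numpy MLP with the fixed dense-dropout-dense-dropout-output layout."""

    def __init__(self, n_features: int, config: DNNConfig | None = None):
        self.config = config or DNNConfig()
        self.config.validate()
        self.n_features = n_features
        rng = np.random.default_rng(np.random.SeedSequence(self.config.seed))
        h = self.config.hidden_units
        n_out = 1 if self.config.output == "sigmoid" else 2
        self.W1 = _glorot(rng, n_features, h)
        self.b1 = np.zeros(h)
        self.W2 = _glorot(rng, h, h)
        self.b2 = np.zeros(h)
        self.W3 = _glorot(rng, h, n_out)
        self.b3 = np.zeros(n_out)
        self._rng = rng
        self.loss_history: list[float] = []

    # ------------------------------------------------------------- forward
    def _forward(self, X: np.ndarray) -> np.ndarray:
        a1 = np.maximum(X @ self.W1 + self.b1, 0.0)
        a2 = np.maximum(a1 @ self.W2 + self.b2, 0.0)
        z3 = a2 @ self.W3 + self.b3
        if self.config.output == "sigmoid":
            return expit(z3[:, 0])
        z3 = z3 - z3.max(axis=1, keepdims=True)
        e = np.exp(z3)
        return (e / e.sum(axis=1, keepdims=True))[:, 1]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probability of the positive (sepsis) class; dropout disabled."""
        return self._forward(np.asarray(X, dtype=float))

    def _loss(self, X: np.ndarray, y: np.ndarray) -> float:
        p = np.clip(self._forward(X), 1e-12, 1.0 - 1e-12)
        ce = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).mean()
        l2 = self.config.l2_lambda * sum(
            float((W**2).sum()) for W in (self.W1, self.W2, self.W3)
        )
        return ce + l2

    # ------------------------------------------------------------ training
    def fit(self, X: np.ndarray, y: np.ndarray) -> "MLPBinaryClassifier":
        cfg = self.config
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n = X.shape[0]
        keep = 1.0 - cfg.dropout_rate
        params = [self.W1, self.b1, self.W2, self.b2, self.W3, self.b3]
        opt = _AdaMax(params, cfg.learning_rate)
        rng = self._rng

        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb, yb = X[idx], y[idx]
                B = len(idx)

                a1 = np.maximum(xb @ self.W1 + self.b1, 0.0)
                m1 = rng.binomial(1, keep, size=a1.shape) / keep
                a1d = a1 * m1
                a2 = np.maximum(a1d @ self.W2 + self.b2, 0.0)
                m2 = rng.binomial(1, keep, size=a2.shape) / keep
                a2d = a2 * m2
                z3 = a2d @ self.W3 + self.b3

                if cfg.output == "sigmoid":
                    p = expit(z3[:, 0])
                    dz3 = ((p - yb) / B)[:, None]
                else:
                    z3s = z3 - z3.max(axis=1, keepdims=True)
                    e = np.exp(z3s)
                    probs = e / e.sum(axis=1, keepdims=True)
                    onehot = np.column_stack([1.0 - yb, yb])
                    dz3 = (probs - onehot) / B

                gW3 = a2d.T @ dz3 + 2.0 * cfg.l2_lambda * self.W3
                gb3 = dz3.sum(axis=0)
                da2 = (dz3 @ self.W3.T) * m2 * (a2 > 0)
                gW2 = a1d.T @ da2 + 2.0 * cfg.l2_lambda * self.W2
                gb2 = da2.sum(axis=0)
                da1 = (da2 @ self.W2.T) * m1 * (a1 > 0)
                gW1 = xb.T @ da1 + 2.0 * cfg.l2_lambda * self.W1
                gb1 = da1.sum(axis=0)

                opt.step(params, [gW1, gb1, gW2, gb2, gW3, gb3])
            self.loss_history.append(self._loss(X, y))
        return self

    # --------------------------------------------------------- persistence
    def get_weights(self) -> dict[str, np.ndarray]:
        return {
            "W1": self.W1, "b1": self.b1,
            "W2": self.W2, "b2": self.b2,
            "W3": self.W3, "b3": self.b3,
        }

    def max_abs_weight(self) -> float:
        return max(float(np.abs(W).max()) for W in (self.W1, self.W2, self.W3))
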