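"""Small gradient-trained regressors satisfying the trainer's model contract.

The bias that skewed losses correct arises for *any* regression model trained
with a symmetric loss, so desk-scale models are enough to exercise the
training controller.  Two are provided:

* :class:`LinearRegressor` — ŷ = Xw + b.
* :class:`MLPRegressor` — one tanh hidden layer over standardized inputs.

A model exposes ``initialize(p, rng)``, ``predict(X)`` and
``backward(X, dl_dyhat)`` returning parameter gradients aligned with
``params``; the trainer owns batching and the optimizer.  ``predict`` is
deterministic given fixed parameters.
"""

from __future__ import annotations

from typing import Protocol

import numpy as np

__all__ = ["GradientRegressor", "LinearRegressor", "MLPRegressor", "Adam"]


class GradientRegressor(Protocol):
    """Behavioral contract consumed by the training loop."""

    params: list[np.ndarray]

    def initialize(self, p: int, rng: np.random.Generator) -> None: ...

    def prepare(self, X: np.ndarray, y: np.ndarray) -> None: ...

    def predict(self, X: np.ndarray) -> np.ndarray: ...

    def backward(self, X: np.ndarray, dl_dyhat: np.ndarray) -> list[np.ndarray]: ...


class LinearRegressor:
    """ŷ = Zw + b over standardized inputs, trained by mini-batch gradient
    descent.  Raw anatomical features are all-positive and strongly
    correlated with each other, which couples the weights to the intercept
    and makes L1 training crawl; standardizing by training-set statistics
    (set in :meth:`prepare`) removes that ill-conditioning without changing
    the model class."""

    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self._mu = 0.0
        self._sd = 1.0

    def initialize(self, p: int, rng: np.random.Generator) -> None:
        w = rng.normal(0.0, 0.01, size=p)
        b = np.zeros(1)
        self.params = [w, b]

    def prepare(self, X: np.ndarray, y: np.ndarray) -> None:
        self._mu = X.mean(axis=0)
        sd = X.std(axis=0)
        self._sd = np.where(sd > 0, sd, 1.0)
        # start the intercept at the mean age so early epochs are informative
        self.params[1][0] = float(np.mean(y))

    def _scale(self, X: np.ndarray) -> np.ndarray:
        return (X - self._mu) / self._sd

    def predict(self, X: np.ndarray) -> np.ndarray:
        w, b = self.params
        return self._scale(X) @ w + b[0]

    def backward(self, X: np.ndarray, dl_dyhat: np.ndarray) -> list[np.ndarray]:
        return [self._scale(X).T @ dl_dyhat, np.array([dl_dyhat.sum()])]

    def state(self) -> dict:
        return {
            "kind": "linear",
            "w": self.params[0].tolist(),
            "b": float(self.params[1][0]),
            "input_mean": np.asarray(self._mu).tolist(),
            "input_sd": np.asarray(self._sd).tolist(),
        }


class MLPRegressor:
    """One-hidden-layer perceptron: ŷ = tanh(Zs W1 + b1) w2 + b2 with inputs
    standardized by training-set statistics (set in :meth:`prepare`)."""

    def __init__(self, hidden: int = 16) -> None:
        self.hidden = hidden
        self.params: list[np.ndarray] = []
        self._mu = 0.0
        self._sd = 1.0

    def initialize(self, p: int, rng: np.random.Generator) -> None:
        h = self.hidden
        w1 = rng.normal(0.0, 1.0 / np.sqrt(p), size=(p, h))
        b1 = np.zeros(h)
        w2 = rng.normal(0.0, 1.0 / np.sqrt(h), size=h)
        b2 = np.zeros(1)
        self.params = [w1, b1, w2, b2]

    def prepare(self, X: np.ndarray, y: np.ndarray) -> None:
        self._mu = X.mean(axis=0)
        self._sd = X.std(axis=0)
        self._sd = np.where(self._sd > 0, self._sd, 1.0)
        self.params[3][0] = float(np.mean(y))

    def _scale(self, X: np.ndarray) -> np.ndarray:
        return (X - self._mu) / self._sd

    def predict(self, X: np.ndarray) -> np.ndarray:
        w1, b1, w2, b2 = self.params
        return np.tanh(self._scale(X) @ w1 + b1) @ w2 + b2[0]

    def backward(self, X: np.ndarray, dl_dyhat: np.ndarray) -> list[np.ndarray]:
        w1, b1, w2, b2 = self.params
        Z = self._scale(X)
        H = np.tanh(Z @ w1 + b1)
        dh = np.outer(dl_dyhat, w2) * (1.0 - H * H)
        return [Z.T @ dh, dh.sum(axis=0), H.T @ dl_dyhat, np.array([dl_dyhat.sum()])]

    def state(self) -> dict:
        return {
            "kind": "mlp",
            "hidden": self.hidden,
            "params": [p.tolist() for p in self.params],
            "input_mean": np.asarray(self._mu).tolist(),
            "input_sd": np.asarray(self._sd).tolist(),
        }


class Adam:
    """Adam with optional coupled L2 weight decay (added to the gradient)."""

    def __init__(self, params: list[np.ndarray], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0) -> None:
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(zip(params, grads)):
            if self.weight_decay:
                g = g + self.weight_decay * p
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)
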