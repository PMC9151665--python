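"""A small fully connected neural-network regressor in pure numpy.

The network mirrors the DNN used for LAI estimation: fully connected layers
with a symmetric ramp of hidden units (default 100, 300, 1000, 1000, 300,
100), ReLU activations, inverted dropout after every hidden layer (default
rate 0.17), mean-squared-error loss, and the Adam optimizer (default
learning rate 1e-3, batch size 100).  Inputs and the target are
standardized internally, so the caller passes raw feature units.

Training is fully deterministic for a given seed: weight initialization,
batch shuffling, and dropout masks all draw from one seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidInputError, TrainingFailureError

__all__ = ["DNNConfig", "MLPRegressor"]


@dataclass(frozen=True)
class DNNConfig:
    """Architecture and optimizer settings for the MLP regressor."""

    hidden_units: tuple[int, ...] = (100, 300, 1000, 1000, 300, 100)
    dropout: float = 0.17
    learning_rate: float = 1e-3
    epochs: int = 1000
    batch_size: int = 100

    def __post_init__(self):
        if not self.hidden_units or any(u < 1 for u in self.hidden_units):
            raise InvalidInputError("hidden_units must be a non-empty tuple of positive ints")
        if not (0 <= self.dropout < 1):
            raise InvalidInputError("dropout must lie in [0, 1)")
        if self.learning_rate <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise InvalidInputError("invalid optimizer setting")


class MLPRegressor:
    """Feed-forward ReLU network trained with Adam on squared error.

    Implements the subset of the scikit-learn estimator interface used by
    the regressor registry: ``fit(X, y)`` and ``predict(X)``.
    """

    def __init__(self, config: DNNConfig = DNNConfig(), seed: int = 0):
        self.config = config
        self.seed = int(seed)
        self.loss_history_: list[float] = []

    # -- initialization -------------------------------------------------
    def _init_weights(self, n_features: int, rng: np.random.Generator):
        sizes = [n_features, *self.config.hidden_units, 1]
        self.W_ = []
        self.b_ = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            # He initialization, appropriate for ReLU layers
            self.W_.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)))
            self.b_.append(np.zeros(fan_out))

    # -- forward / backward ---------------------------------------------
    def _forward(self, X, rng=None):
        """Forward pass; returns activations and dropout masks for backprop."""
        p = self.config.dropout
        acts = [X]
        masks = []
        h = X
        for i, (W, b) in enumerate(zip(self.W_, self.b_)):
            z = h @ W + b
            if i < len(self.W_) - 1:
                h = np.maximum(z, 0.0)
                if rng is not None and p > 0:
                    mask = (rng.random(h.shape) >= p) / (1.0 - p)
                    h = h * mask
                else:
                    mask = None
                masks.append(mask)
            else:
                h = z
            acts.append(h)
        return acts, masks

    def _adam_step(self, grads_W, grads_b):
        c = self.config
        self._t += 1
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        for i in range(len(self.W_)):
            for params, grads, m, v in (
                (self.W_, grads_W, self._mW, self._vW),
                (self.b_, grads_b, self._mb, self._vb),
            ):
                m[i] = beta1 * m[i] + (1 - beta1) * grads[i]
                v[i] = beta2 * v[i] + (1 - beta2) * grads[i] ** 2
                mhat = m[i] / (1 - beta1 ** self._t)
                vhat = v[i] / (1 - beta2 ** self._t)
                params[i] -= c.learning_rate * mhat / (np.sqrt(vhat) + eps)

    # -- public API ------------------------------------------------------
    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or len(X) != len(y):
            raise InvalidInputError("X must be 2-D with one row per target value")
        rng = np.random.default_rng(self.seed)
        self._x_mean, self._x_std = X.mean(axis=0), X.std(axis=0)
        self._x_std[self._x_std == 0] = 1.0
        self._y_mean, self._y_std = y.mean(), y.std()
        self._constant_fit = self._y_std == 0
        if self._constant_fit:
            # degenerate target: the optimal regression is the constant itself
            self._y_std = 1.0
            self.loss_history_ = [0.0]
            return self
        Xs = (X - self._x_mean) / self._x_std
        ys = (y - self._y_mean) / self._y_std

        self._init_weights(X.shape[1], rng)
        self._mW = [np.zeros_like(w) for w in self.W_]
        self._vW = [np.zeros_like(w) for w in self.W_]
        self._mb = [np.zeros_like(b) for b in self.b_]
        self._vb = [np.zeros_like(b) for b in self.b_]
        self._t = 0
        self.loss_history_ = []

        n = len(Xs)
        bs = min(self.config.batch_size, n)
        for epoch in range(self.config.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                xb, yb = Xs[idx], ys[idx]
                acts, masks = self._forward(xb, rng=rng)
                pred = acts[-1].ravel()
                resid = pred - yb
                epoch_loss += float(resid @ resid)
                # backprop of mean-squared-error through the ReLU stack
                delta = (2.0 / len(idx)) * resid[:, None]
                grads_W = [None] * len(self.W_)
                grads_b = [None] * len(self.b_)
                for i in range(len(self.W_) - 1, -1, -1):
                    grads_W[i] = acts[i].T @ delta
                    grads_b[i] = delta.sum(axis=0)
                    if i > 0:
                        delta = delta @ self.W_[i].T
                        if masks[i - 1] is not None:
                            delta = delta * masks[i - 1]
                        delta = delta * (acts[i] > 0)
                self._adam_step(grads_W, grads_b)
            epoch_loss /= n
            if not np.isfinite(epoch_loss):
                raise TrainingFailureError(
                    f"non-finite loss at epoch {epoch}",
                    diagnostics={"epoch": epoch, "loss_history": self.loss_history_},
                )
            self.loss_history_.append(epoch_loss)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if self._constant_fit:
            return np.full(len(X), self._y_mean)
        Xs = (X - self._x_mean) / self._x_std
        acts, _ = self._forward(Xs, rng=None)
        return acts[-1].ravel() * self._y_std + self._y_mean

    # scikit-learn compatibility hooks used by the registry
    def get_params(self, deep=True):
        return {"config": self.config, "seed": self.seed}
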