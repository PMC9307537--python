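"""Minimal CPU neural-network building blocks.

The classifiers and regressors in this package are *fixed-feature
convolutional networks*: a seed-deterministic convolutional encoder (random
filters, never trained) followed by a trainable head optimised with Adam.
Random convolutional features are a well-understood approximation to a
trained encoder at small scale, they keep training CPU-cheap, and they make
every model run exactly reproducible from its seed.

Everything here is deliberately framework-free numpy; the encoders use
scipy's C-level convolution routines.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "Adam",
    "ConvEncoder2D",
    "ResidualEncoder1D",
    "MLPHead",
    "Standardizer",
]


class Adam:
    """Adam optimiser over a list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class ConvEncoder2D:
    """Fixed random 2-D convolutional encoder for grayscale frames.

    ``n_filters`` random kernels are correlated with each frame, passed
    through ReLU, and adaptively average-pooled to a ``pool x pool`` grid,
    giving ``n_filters * pool**2`` features per frame.
    """

    def __init__(self, n_filters: int = 8, kernel: int = 5, pool: int = 2, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.kernels = rng.standard_normal((n_filters, kernel, kernel)) / kernel
        self.pool = pool

    @property
    def n_features(self) -> int:
        return self.kernels.shape[0] * self.pool**2

    def encode(self, frames: np.ndarray) -> np.ndarray:
        """(N, H, W) frame stack -> (N, n_features) feature matrix."""
        frames = np.asarray(frames, dtype=np.float64)
        if frames.ndim == 2:
            frames = frames[None]
        n, h, w = frames.shape
        p = self.pool
        feats = np.empty((n, self.kernels.shape[0], p, p))
        hb = np.linspace(0, h, p + 1).astype(int)
        wb = np.linspace(0, w, p + 1).astype(int)
        for fi, k in enumerate(self.kernels):
            resp = ndimage.correlate(frames, k[None, :, :], mode="reflect")
            np.maximum(resp, 0.0, out=resp)
            for a in range(p):
                for b in range(p):
                    feats[:, fi, a, b] = resp[:, hb[a]:hb[a + 1], wb[b]:wb[b + 1]].mean(
                        axis=(1, 2)
                    )
        return feats.reshape(n, -1)


class ResidualEncoder1D:
    """Fixed random 1-D residual convolutional encoder for motion signals.

    Input: a (C, T) multi-channel signal.  A channel-mixing input
    convolution is followed by ``n_blocks`` residual blocks
    (conv-ReLU-conv + identity, then ReLU), producing a per-time-step
    feature matrix (T, n_channels).
    """

    def __init__(self, in_channels: int = 3, n_channels: int = 16,
                 kernel: int = 5, n_blocks: int = 2, seed: int = 0):
        rng = np.random.default_rng(seed)
        scale = 1.0 / np.sqrt(kernel * max(in_channels, n_channels))
        self.w_in = rng.standard_normal((n_channels, in_channels, kernel)) * scale
        self.blocks = [
            (
                rng.standard_normal((n_channels, n_channels, kernel)) * scale,
                rng.standard_normal((n_channels, n_channels, kernel)) * scale,
            )
            for _ in range(n_blocks)
        ]
        self.n_channels = n_channels

    @staticmethod
    def _conv(x: np.ndarray, w: np.ndarray) -> np.ndarray:
        """(C_in, T) x (C_out, C_in, K) -> (C_out, T), reflect-padded."""
        c_out = w.shape[0]
        out = np.zeros((c_out, x.shape[1]))
        for o in range(c_out):
            for i in range(x.shape[0]):
                out[o] += ndimage.correlate1d(x[i], w[o, i], mode="reflect")
        return out

    def encode(self, omega: np.ndarray) -> np.ndarray:
        """(C, T) signal -> (T, n_channels) per-time-step features."""
        x = np.maximum(self._conv(np.asarray(omega, dtype=np.float64), self.w_in), 0.0)
        for w1, w2 in self.blocks:
            y = self._conv(np.maximum(self._conv(x, w1), 0.0), w2)
            x = np.maximum(x + y, 0.0)
        return x.T


class Standardizer:
    """Feature z-scoring with statistics frozen from the training set."""

    def fit(self, x: np.ndarray) -> "Standardizer":
        self.mean = x.mean(axis=0)
        self.sd = x.std(axis=0)
        self.sd[self.sd == 0] = 1.0
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.sd


class MLPHead:
    """Trainable head: optional single hidden layer, linear output.

    ``task='binary'`` applies a sigmoid and trains with cross-entropy;
    ``task='regression'`` is linear output with MSE loss.  Weights are
    initialised from ``seed``; :meth:`snapshot`/:meth:`restore` support
    best-epoch checkpointing.
    """

    def __init__(self, n_in: int, hidden: int = 0, task: str = "binary", seed: int = 0):
        rng = np.random.default_rng(seed)
        self.task = task
        self.hidden = hidden
        if hidden:
            self.w1 = rng.standard_normal((n_in, hidden)) / np.sqrt(n_in)
            self.b1 = np.zeros(hidden)
            self.w2 = rng.standard_normal((hidden, 1)) / np.sqrt(hidden)
            self.b2 = np.zeros(1)
            self.params = [self.w1, self.b1, self.w2, self.b2]
        else:
            self.w2 = rng.standard_normal((n_in, 1)) / np.sqrt(n_in)
            self.b2 = np.zeros(1)
            self.params = [self.w2, self.b2]

    # forward -------------------------------------------------------------
    def _forward(self, x: np.ndarray):
        if self.hidden:
            a = x @ self.w1 + self.b1
            h = np.maximum(a, 0.0)
            z = (h @ self.w2 + self.b2).ravel()
            return z, (x, a, h)
        z = (x @ self.w2 + self.b2).ravel()
        return z, (x,)

    def predict(self, x: np.ndarray) -> np.ndarray:
        z, _ = self._forward(np.asarray(x, dtype=np.float64))
        if self.task == "binary":
            return 1.0 / (1.0 + np.exp(-z))
        return z

    # training ------------------------------------------------------------
    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        n = x.shape[0]
        z, cache = self._forward(x)
        if self.task == "binary":
            p = 1.0 / (1.0 + np.exp(-z))
            eps = 1e-12
            loss = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
            dz = (p - y) / n
        else:
            loss = np.mean((z - y) ** 2)
            dz = 2.0 * (z - y) / n
        if self.hidden:
            x_in, a, h = cache
            gw2 = h.T @ dz[:, None]
            gb2 = np.array([dz.sum()])
            dh = dz[:, None] @ self.w2.T
            dh[a <= 0] = 0.0
            gw1 = x_in.T @ dh
            gb1 = dh.sum(axis=0)
            return loss, [gw1, gb1, gw2, gb2]
        x_in, = cache
        return loss, [x_in.T @ dz[:, None], np.array([dz.sum()])]

    def fit(
        self,
        x_train: np.ndarray,
        y_train: np.ndarray,
        x_val: np.ndarray,
        y_val: np.ndarray,
        *,
        lr: float = 1e-4,
        batch: int = 64,
        epochs: int = 50,
        seed: int = 0,
        val_metric=None,
        higher_is_better: bool = True,
        patience: int | None = None,
        weight_decay: float = 0.0,
    ):
        """Minibatch Adam training with per-epoch validation checkpointing.

        ``val_metric(y_val, pred_val) -> float`` drives model selection
        (default: negative validation loss).  Returns a history dict with
        per-epoch train losses and validation metrics; the best epoch's
        weights are restored before returning.
        """
        rng = np.random.default_rng(seed)
        opt = Adam(self.params, lr=lr)
        n = x_train.shape[0]
        history = {"train_loss": [], "val_metric": [], "best_epoch": -1}
        best = -np.inf
        best_state = [p.copy() for p in self.params]
        stale = 0
        for epoch in range(epochs):
            order = rng.permutation(n)
            ep_loss = 0.0
            for start in range(0, n, batch):
                idx = order[start:start + batch]
                loss, grads = self.loss_and_grads(x_train[idx], y_train[idx])
                if weight_decay:
                    # L2 penalty on weight matrices only (not biases)
                    for p, g in zip(self.params, grads):
                        if p.ndim == 2:
                            g += 2.0 * weight_decay * p
                opt.step(grads)
                ep_loss += loss * len(idx)
            history["train_loss"].append(ep_loss / n)
            pred_val = self.predict(x_val)
            if val_metric is None:
                metric = -float(np.mean((pred_val - y_val) ** 2))
            else:
                metric = float(val_metric(y_val, pred_val))
                if not higher_is_better:
                    metric = -metric
            history["val_metric"].append(metric)
            if metric > best:
                best = metric
                best_state = [p.copy() for p in self.params]
                history["best_epoch"] = epoch
                stale = 0
            else:
                stale += 1
                if patience is not None and stale > patience:
                    break
        for p, s in zip(self.params, best_state):
            p[...] = s
        return history
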