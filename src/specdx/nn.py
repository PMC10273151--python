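"""A small 1D convolutional network for spectral scoring, in pure NumPy.

The scoring model maps a 1,025-point normalized spectrum to the logit of
the probability that the probed tissue is invasive adenocarcinoma.  The
default architecture is deliberately small -- two conv/ReLU/max-pool
blocks, global average pooling and a single hidden dense layer -- the
smallest network that separates the synthetic classes in minutes on one
CPU core.  Training minimises binary cross-entropy with Adam; forward
and backward passes are fully vectorised (im2col convolutions), and all
randomness (initialisation, batch shuffling) flows from one seed, so a
fixed seed reproduces training bit-for-bit.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["NetConfig", "SpectralCNN", "sigmoid", "bce_with_logits"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy, numerically stable in the logits."""
    return float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))


@dataclasses.dataclass(frozen=True)
class NetConfig:
    in_channels: int = 1
    conv_channels: tuple[int, int] = (8, 16)
    kernel_width: int = 9
    pool: int = 4
    dense_width: int = 32
    learning_rate: float = 3e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], cfg: NetConfig) -> None:
        self.cfg = cfg
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        c = self.cfg
        self.t += 1
        bc1 = 1.0 - c.beta1 ** self.t
        bc2 = 1.0 - c.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = c.beta1 * self.m[k] + (1 - c.beta1) * g
            self.v[k] = c.beta2 * self.v[k] + (1 - c.beta2) * g * g
            params[k] -= c.learning_rate * (self.m[k] / bc1) / (
                np.sqrt(self.v[k] / bc2) + c.eps
            )


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Valid 1D convolution.  x: (N, C, L); w: (O, C, K) -> (N, O, L-K+1)."""
    windows = sliding_window_view(x, w.shape[2], axis=2)  # (N, C, L', K)
    y = np.einsum("nclk,ock->nol", windows, w, optimize=True) + b[None, :, None]
    return y, windows


def _conv_backward(dy: np.ndarray, windows: np.ndarray, w: np.ndarray, x_shape):
    dw = np.einsum("nol,nclk->ock", dy, windows, optimize=True)
    db = dy.sum(axis=(0, 2))
    dx = np.zeros(x_shape, dtype=dy.dtype)
    lp = dy.shape[2]
    for j in range(w.shape[2]):
        dx[:, :, j : j + lp] += np.einsum("nol,oc->ncl", dy, w[:, :, j], optimize=True)
    return dx, dw, db


def _maxpool_forward(x: np.ndarray, size: int):
    n, c, l = x.shape
    lp = l // size
    xr = x[:, :, : lp * size].reshape(n, c, lp, size)
    idx = xr.argmax(axis=3)
    y = np.take_along_axis(xr, idx[..., None], axis=3)[..., 0]
    return y, (idx, x.shape, lp)


def _maxpool_backward(dy: np.ndarray, cache, size: int) -> np.ndarray:
    idx, x_shape, lp = cache
    n, c, _ = x_shape
    dxr = np.zeros((n, c, lp, size), dtype=dy.dtype)
    np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=3)
    dx = np.zeros(x_shape, dtype=dy.dtype)
    dx[:, :, : lp * size] = dxr.reshape(n, c, lp * size)
    return dx


class SpectralCNN:
    """Conv(k)->ReLU->pool -> Conv(k)->ReLU->pool -> GAP -> Dense -> logit."""

    def __init__(self, cfg: NetConfig = NetConfig(), seed: int = 0) -> None:
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        c1, c2 = cfg.conv_channels
        k = cfg.kernel_width

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)

        self.params: dict[str, np.ndarray] = {
            "w1": he((c1, cfg.in_channels, k), cfg.in_channels * k),
            "b1": np.zeros(c1, dtype=np.float32),
            "w2": he((c2, c1, k), c1 * k),
            "b2": np.zeros(c2, dtype=np.float32),
            "w3": he((cfg.dense_width, c2), c2),
            "b3": np.zeros(cfg.dense_width, dtype=np.float32),
            "w4": he((1, cfg.dense_width), cfg.dense_width),
            "b4": np.zeros(1, dtype=np.float32),
        }
        self._opt = _Adam(self.params, cfg)

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, need_cache: bool = False):
        """x: (N, C, L) float32 -> logits (N,)."""
        p = self.params
        z1, win1 = _conv_forward(x, p["w1"], p["b1"])
        a1 = np.maximum(z1, 0.0)
        p1, cache1 = _maxpool_forward(a1, self.cfg.pool)
        z2, win2 = _conv_forward(p1, p["w2"], p["b2"])
        a2 = np.maximum(z2, 0.0)
        p2, cache2 = _maxpool_forward(a2, self.cfg.pool)
        g = p2.mean(axis=2)  # global average pool -> (N, C2)
        h = np.maximum(g @ p["w3"].T + p["b3"], 0.0)
        logits = (h @ p["w4"].T + p["b4"]).ravel()
        if not need_cache:
            return logits, None
        return logits, (x, win1, z1, cache1, p1, win2, z2, cache2, p2, g, h)

    def _backward(self, logits: np.ndarray, y: np.ndarray, cache) -> dict[str, np.ndarray]:
        p = self.params
        x, win1, z1, cache1, p1, win2, z2, cache2, p2, g, h = cache
        n = x.shape[0]
        dz = ((sigmoid(logits) - y) / n).astype(np.float32)  # dL/dlogit
        dw4 = dz[None, :] @ h
        db4 = np.array([dz.sum()], dtype=np.float32)
        dh = dz[:, None] @ p["w4"]
        dh[h <= 0] = 0.0
        dw3 = dh.T @ g
        db3 = dh.sum(axis=0)
        dg = dh @ p["w3"]
        dp2 = np.repeat(dg[:, :, None] / p2.shape[2], p2.shape[2], axis=2).astype(
            np.float32
        )
        da2 = _maxpool_backward(dp2, cache2, self.cfg.pool)
        da2[z2 <= 0] = 0.0
        dp1, dw2, db2 = _conv_backward(da2, win2, p["w2"], p1.shape)
        da1 = _maxpool_backward(dp1, cache1, self.cfg.pool)
        da1[z1 <= 0] = 0.0
        _, dw1, db1 = _conv_backward(da1, win1, p["w1"], x.shape)
        return {
            "w1": dw1, "b1": db1, "w2": dw2, "b2": db2,
            "w3": dw3, "b3": db3, "w4": dw4.astype(np.float32), "b4": db4,
        }

    # -- training / inference ----------------------------------------------

    def train_step(self, x: np.ndarray, y: np.ndarray) -> float:
        logits, cache = self.forward(x, need_cache=True)
        loss = bce_with_logits(logits, y)
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite training loss; aborting")
        grads = self._backward(logits, y, cache)
        self._opt.step(self.params, grads)
        return loss

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int,
        batch_size: int,
        rng: np.random.Generator,
    ) -> list[float]:
        """Mini-batch Adam training; returns the mean loss per epoch."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        y = np.asarray(y, dtype=np.float32)
        n = x.shape[0]
        history: list[float] = []
        for _ in range(epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                losses.append(self.train_step(x[idx], y[idx]))
            history.append(float(np.mean(losses)))
        return history

    def predict_proba(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        out = np.empty(x.shape[0], dtype=np.float64)
        for start in range(0, x.shape[0], batch_size):
            logits, _ = self.forward(x[start : start + batch_size])
            out[start : start + batch_size] = sigmoid(logits.astype(np.float64))
        return out

    # -- (de)serialisation ---------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=np.float32)
        self._opt = _Adam(self.params, self.cfg)
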