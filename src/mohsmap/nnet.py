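"""Minimal convolutional network implemented on numpy.

A small feature extractor (two valid 3x3 convolution blocks, each followed
by ReLU and 2x2 max-pooling) feeding exactly three dense ReLU layers and a
final linear layer whose softmax gives class probabilities.  Forward and
backward passes are exact (im2col via stride tricks); optimization is Adam
on the categorical cross-entropy.  Everything is float64 and fully
deterministic given the initializing Generator.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Valid cross-correlation. x: (N,H,W,C), W: (k,k,C,F) -> (N,H-k+1,W-k+1,F)."""
    k = W.shape[0]
    cols = sliding_window_view(x, (k, k), axis=(1, 2))  # (N, H', W', C, k, k)
    out = np.einsum("nhwcij,ijcf->nhwf", cols, W, optimize=True) + b
    return out, cols


def _conv_backward(x_shape, cols, W, dout):
    dW = np.einsum("nhwcij,nhwf->ijcf", cols, dout, optimize=True)
    db = dout.sum(axis=(0, 1, 2))
    k = W.shape[0]
    pad = k - 1
    dpad = np.pad(dout, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    cols2 = sliding_window_view(dpad, (k, k), axis=(1, 2))  # (N, H, W, F, k, k)
    Wflip = W[::-1, ::-1]
    dx = np.einsum("nhwfij,ijcf->nhwc", cols2, Wflip, optimize=True)
    assert dx.shape == x_shape
    return dx, dW, db


def _pool_forward(x: np.ndarray):
    """2x2 max pool, stride 2, floor semantics (odd trailing row/col dropped)."""
    n, h, w, c = x.shape
    h2, w2 = h // 2, w // 2
    xc = x[:, : h2 * 2, : w2 * 2].reshape(n, h2, 2, w2, 2, c)
    out = xc.max(axis=(2, 4))
    return out, (x.shape, xc, out)


def _pool_backward(cache, dout):
    x_shape, xc, out = cache
    mask = xc == out[:, :, None, :, None, :]
    counts = mask.sum(axis=(2, 4), keepdims=True)  # split gradient across ties
    dx_c = mask * (dout[:, :, None, :, None, :] / counts)
    n, h, w, c = x_shape
    h2, w2 = h // 2, w // 2
    dx = np.zeros(x_shape)
    dx[:, : h2 * 2, : w2 * 2] = dx_c.reshape(n, h2 * 2, w2 * 2, c)
    return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray, sample_weight=None) -> float:
    """(Weighted) mean categorical cross-entropy; y is an integer class vector."""
    eps = 1e-12
    nll = -np.log(probs[np.arange(len(y)), y] + eps)
    if sample_weight is None:
        return float(nll.mean())
    w = np.asarray(sample_weight, dtype=float)
    return float((nll * w).sum() / w.sum())


class SmallConvNet:
    """Two conv blocks + three dense ReLU layers + linear head (softmax output)."""

    def __init__(
        self,
        input_size: int,
        dense_widths: tuple[int, int, int],
        n_classes: int,
        rng: np.random.Generator,
        conv_filters: tuple[int, int] = (8, 16),
    ):
        if len(dense_widths) != 3:
            raise ValueError("exactly three dense layers are required")
        if input_size < 10:
            raise ValueError("input_size must be >= 10 for two conv/pool blocks")
        f1, f2 = conv_filters
        s1 = input_size - 2
        p1 = s1 // 2
        s2 = p1 - 2
        p2 = s2 // 2
        self.input_size = input_size
        self.n_classes = n_classes
        self.flat_dim = p2 * p2 * f2
        d1, d2, d3 = dense_widths

        def he(shape, fan_in):
            return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)

        self.params: dict[str, np.ndarray] = {
            "Wc1": he((3, 3, 3, f1), 27),
            "bc1": np.zeros(f1),
            "Wc2": he((3, 3, f1, f2), 9 * f1),
            "bc2": np.zeros(f2),
            "W1": he((self.flat_dim, d1), self.flat_dim),
            "b1": np.zeros(d1),
            "W2": he((d1, d2), d1),
            "b2": np.zeros(d2),
            "W3": he((d2, d3), d2),
            "b3": np.zeros(d3),
            "Wout": he((d3, n_classes), d3),
            "bout": np.zeros(n_classes),
        }

    def forward(self, x: np.ndarray):
        p = self.params
        c1, cols1 = _conv_forward(x, p["Wc1"], p["bc1"])
        r1 = np.maximum(c1, 0)
        pl1, cache_p1 = _pool_forward(r1)
        c2, cols2 = _conv_forward(pl1, p["Wc2"], p["bc2"])
        r2 = np.maximum(c2, 0)
        pl2, cache_p2 = _pool_forward(r2)
        flat = pl2.reshape(len(x), -1)
        h1 = np.maximum(flat @ p["W1"] + p["b1"], 0)
        h2 = np.maximum(h1 @ p["W2"] + p["b2"], 0)
        h3 = np.maximum(h2 @ p["W3"] + p["b3"], 0)
        logits = h3 @ p["Wout"] + p["bout"]
        cache = (x, cols1, c1, cache_p1, pl1, cols2, c2, cache_p2, pl2, flat, h1, h2, h3)
        return logits, cache

    def backward(self, cache, dlogits):
        p = self.params
        x, cols1, c1, cache_p1, pl1, cols2, c2, cache_p2, pl2, flat, h1, h2, h3 = cache
        g: dict[str, np.ndarray] = {}
        g["Wout"] = h3.T @ dlogits
        g["bout"] = dlogits.sum(axis=0)
        dh3 = (dlogits @ p["Wout"].T) * (h3 > 0)
        g["W3"] = h2.T @ dh3
        g["b3"] = dh3.sum(axis=0)
        dh2 = (dh3 @ p["W3"].T) * (h2 > 0)
        g["W2"] = h1.T @ dh2
        g["b2"] = dh2.sum(axis=0)
        dh1 = (dh2 @ p["W2"].T) * (h1 > 0)
        g["W1"] = flat.T @ dh1
        g["b1"] = dh1.sum(axis=0)
        dflat = dh1 @ p["W1"].T
        dpl2 = dflat.reshape(pl2.shape)
        dr2 = _pool_backward(cache_p2, dpl2)
        dc2 = dr2 * (c2 > 0)
        dpl1, g["Wc2"], g["bc2"] = _conv_backward(pl1.shape, cols2, p["Wc2"], dc2)
        dr1 = _pool_backward(cache_p1, dpl1)
        dc1 = dr1 * (c1 > 0)
        _, g["Wc1"], g["bc1"] = _conv_backward(x.shape, cols1, p["Wc1"], dc1)
        return g

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray, sample_weight=None):
        logits, cache = self.forward(x)
        probs = softmax(logits)
        loss = cross_entropy(probs, y, sample_weight)
        dlogits = probs.copy()
        dlogits[np.arange(len(y)), y] -= 1.0
        if sample_weight is None:
            dlogits /= len(y)
        else:
            w = np.asarray(sample_weight, dtype=float)
            dlogits *= (w / w.sum())[:, None]
        return loss, self.backward(cache, dlogits)

    def loss(self, x: np.ndarray, y: np.ndarray, batch_size: int = 512,
             sample_weight=None) -> float:
        total, wtotal = 0.0, 0.0
        for i in range(0, len(x), batch_size):
            xb, yb = x[i : i + batch_size], y[i : i + batch_size]
            probs = softmax(self.forward(xb)[0])
            wb = None if sample_weight is None else sample_weight[i : i + batch_size]
            bw = len(xb) if wb is None else float(np.sum(wb))
            total += cross_entropy(probs, yb, wb) * bw
            wtotal += bw
        return total / wtotal

    def predict_proba(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            logits, _ = self.forward(x[i : i + batch_size])
            out.append(softmax(logits))
        return np.concatenate(out, axis=0)

    def get_state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = state[k].copy()


class Adam:
    """Adaptive-moment optimizer over a named parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for k, gk in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * gk
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * gk**2
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
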