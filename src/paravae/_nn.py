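"""Minimal numpy conv-net primitives used by the VAE.

All layers are fixed to the geometry the encoder/decoder need: 4x4 kernels,
stride 2, padding 1, so a conv halves and a transposed conv doubles the
spatial side exactly.  Forward passes are im2col matmuls (BLAS-bound);
backward passes are the exact adjoints, checked against finite differences
in the test suite.  Everything is float64 for reproducibility across runs.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

K = 4  # kernel side; stride 2, pad 1 throughout


def _pad(x: np.ndarray) -> np.ndarray:
    return np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))


def _gather(xp: np.ndarray) -> np.ndarray:
    """(B,C,H+2,W+2) -> contiguous windows (B,Ho,Wo,C,K,K) at stride 2."""
    w = sliding_window_view(xp, (K, K), axis=(2, 3))[:, :, ::2, ::2]
    return np.ascontiguousarray(w.transpose(0, 2, 3, 1, 4, 5))


def _scatter(cols: np.ndarray, H: int, W: int) -> np.ndarray:
    """Adjoint of :func:`_gather`: (B,Ho,Wo,C,K,K) -> (B,C,H,W)."""
    B, Ho, Wo, C = cols.shape[:4]
    out = np.zeros((B, C, H + 2, W + 2))
    d = cols.transpose(0, 3, 1, 2, 4, 5)  # (B,C,Ho,Wo,K,K)
    for i in range(K):
        for j in range(K):
            out[:, :, i:i + 2 * Ho:2, j:j + 2 * Wo:2] += d[..., i, j]
    return out[:, :, 1:-1, 1:-1]


# ---------------------------------------------------------------------------
# strided conv:  (B,C,H,W) -> (B,F,H/2,W/2),  weight (F,C,K,K)

def conv_forward(x, w, b):
    B, C, H, _ = x.shape
    F = w.shape[0]
    cols = _gather(_pad(x))                       # (B,Ho,Wo,C,K,K)
    Ho, Wo = cols.shape[1], cols.shape[2]
    mat = cols.reshape(B * Ho * Wo, C * K * K)
    out = mat @ w.reshape(F, -1).T + b
    return out.reshape(B, Ho, Wo, F).transpose(0, 3, 1, 2), (x.shape, mat)


def conv_backward(dout, w, cache):
    (B, C, H, W), mat = cache
    F = w.shape[0]
    Ho, Wo = dout.shape[2], dout.shape[3]
    dmat = dout.transpose(0, 2, 3, 1).reshape(-1, F)
    dw = (dmat.T @ mat).reshape(w.shape)
    db = dmat.sum(axis=0)
    dcols = (dmat @ w.reshape(F, -1)).reshape(B, Ho, Wo, C, K, K)
    dx = _scatter(dcols, H, W)
    return dx, dw, db


# ---------------------------------------------------------------------------
# transposed conv:  (B,F,H,W) -> (B,C,2H,2W),  weight (F,C,K,K)

def convT_forward(x, w, b):
    B, F, H, W = x.shape
    C = w.shape[1]
    mat = x.transpose(0, 2, 3, 1).reshape(-1, F)
    cols = (mat @ w.reshape(F, -1)).reshape(B, H, W, C, K, K)
    out = _scatter(cols, 2 * H, 2 * W) + b[None, :, None, None]
    return out, (x.shape, mat)


def convT_backward(dout, w, cache):
    (B, F, H, W), mat = cache
    C = w.shape[1]
    g = _gather(_pad(dout))                       # (B,H,W,C,K,K)
    gmat = g.reshape(B * H * W, C * K * K)
    dx = (gmat @ w.reshape(F, -1).T).reshape(B, H, W, F).transpose(0, 3, 1, 2)
    dw = (mat.T @ gmat).reshape(w.shape)
    db = dout.sum(axis=(0, 2, 3))
    return dx, dw, db


# ---------------------------------------------------------------------------
# dense / activations

def linear_forward(x, w, b):
    return x @ w.T + b, x


def linear_backward(dout, w, x):
    return dout @ w, dout.T @ x, dout.sum(axis=0)


def leaky_relu_forward(x, slope=0.2):
    mask = x >= 0
    return np.where(mask, x, slope * x), (mask, slope)


def leaky_relu_backward(dout, cache):
    mask, slope = cache
    return np.where(mask, dout, slope * dout)


def sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))  # numerically stable logistic


def sigmoid_backward(dout, y):
    return dout * y * (1.0 - y)


# ---------------------------------------------------------------------------
# parameter init and optimizer

def he_conv(rng, f, c):
    return rng.normal(0.0, np.sqrt(2.0 / (c * K * K)), size=(f, c, K, K))


def he_linear(rng, out_dim, in_dim):
    return rng.normal(0.0, np.sqrt(2.0 / in_dim), size=(out_dim, in_dim))


class Adam:
    """Adam with bias correction over a dict of named parameters."""

    def __init__(self, params: dict, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        c1 = 1.0 - self.b1 ** self.t
        c2 = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / c1) / (np.sqrt(self.v[k] / c2) + self.eps)
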