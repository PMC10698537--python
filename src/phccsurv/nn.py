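"""Minimal numpy neural-network primitives for the dual-pathway segmentation CNN.

Implements just what the segmentation model needs: same-padded stride-1 2-D
convolution (im2col), ReLU, sigmoid, pixel-weighted binary cross-entropy, and
an Adam optimizer. Forward passes cache what the backward pass needs; all
randomness flows through an explicit ``numpy`` Generator, so training is
bit-reproducible on a fixed seed (single-threaded BLAS assumed for strict
bitwise identity across machines).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2D", "Adam", "relu", "sigmoid", "weighted_bce", "he_init"]


def he_init(rng: np.random.Generator, k: int, c_in: int, c_out: int) -> np.ndarray:
    """He-normal initialization for a (k, k, c_in, c_out) convolution kernel."""
    std = np.sqrt(2.0 / (k * k * c_in))
    return rng.standard_normal((k, k, c_in, c_out)) * std


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Conv2D:
    """Same-padded stride-1 convolution over NHWC tensors."""

    def __init__(self, weight: np.ndarray, bias: np.ndarray):
        self.weight = weight  # (k, k, c_in, c_out)
        self.bias = bias  # (c_out,)
        self._cols: np.ndarray | None = None
        self._in_shape: tuple | None = None

    @classmethod
    def create(cls, rng: np.random.Generator, k: int, c_in: int, c_out: int) -> "Conv2D":
        return cls(he_init(rng, k, c_in, c_out), np.zeros(c_out))

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.weight.shape[0]
        n, h, w, c = x.shape
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        # win: (n, h, w, c, k, k) -> (n*h*w, k*k*c) matching weight layout (k,k,c,·)
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(n * h * w, k * k * c)
        self._cols, self._in_shape = cols, x.shape
        out = cols @ self.weight.reshape(-1, self.weight.shape[-1]) + self.bias
        return out.reshape(n, h, w, -1)

    def backward(self, dout: np.ndarray, need_dx: bool = True):
        """Gradients given dL/dout; returns (dweight, dbias, dx or None)."""
        if self._cols is None:
            raise RuntimeError("backward called before forward")
        k, _, c_in, c_out = self.weight.shape
        n, h, w, _ = self._in_shape
        dflat = dout.reshape(n * h * w, c_out)
        dw = (self._cols.T @ dflat).reshape(self.weight.shape)
        db = dflat.sum(axis=0)
        dx = None
        if need_dx:
            dcols = (dflat @ self.weight.reshape(-1, c_out).T).reshape(n, h, w, k, k, c_in)
            p = k // 2
            dxp = np.zeros((n, h + 2 * p, w + 2 * p, c_in))
            for i in range(k):
                for j in range(k):
                    dxp[:, i : i + h, j : j + w, :] += dcols[:, :, :, i, j, :]
            dx = dxp[:, p : p + h, p : p + w, :]
        return dw, db, dx

    @property
    def params(self) -> list[np.ndarray]:
        return [self.weight, self.bias]


def weighted_bce(p: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Pixel-weighted binary cross-entropy.

    ``w`` holds per-pixel weights (e.g., class weights indexed by the label).
    Returns (mean weighted loss, dL/dlogits) — the gradient is taken with
    respect to the pre-sigmoid logits, for which it is w*(p - y)/norm.
    """
    eps = 1e-12
    norm = w.sum()
    loss = -(w * (y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))).sum() / norm
    dlogits = w * (p - y) / norm
    return loss, dlogits


class Adam:
    """Adam over a flat list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray], mask: list[bool] | None = None) -> None:
        """Apply one update; entries where ``mask`` is False are frozen."""
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(zip(self.params, grads)):
            if mask is not None and not mask[i]:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
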