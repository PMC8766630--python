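"""Minimal CNN layers on numpy with explicit forward/backward passes.

All layers operate on a single image laid out channel-first, ``(C, H, W)``
(the training batch size is 1 throughout).  Each layer caches what its
backward pass needs; ``backward`` consumes the upstream gradient and
returns the gradient with respect to the input, accumulating parameter
gradients on the layer.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def truncated_normal(rng: np.random.Generator, shape, std: float = 0.1, trunc: float = 2.0):
    """Truncated-normal init: mean 0, given std, re-drawn beyond +-trunc*std."""
    out = rng.standard_normal(shape)
    bad = np.abs(out) > trunc
    while np.any(bad):
        out[bad] = rng.standard_normal(bad.sum())
        bad = np.abs(out) > trunc
    return out * std


class Layer:
    params: list
    grads: list

    def __init__(self):
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3x3(Layer):
    """3x3 convolution, stride 1, zero 'same' padding, via im2col."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.W = truncated_normal(rng, (c_out, c_in * 9))
        self.b = np.zeros(c_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
        win = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (c, h, w, 3, 3)
        return win.transpose(0, 3, 4, 1, 2).reshape(c * 9, h * w)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        self._cols = self._im2col(x)
        h, w = x.shape[1:]
        return (self.W @ self._cols + self.b[:, None]).reshape(self.c_out, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        c, h, w = self._shape
        dflat = dout.reshape(self.c_out, -1)
        self.grads[0] += dflat @ self._cols.T
        self.grads[1] += dflat.sum(axis=1)
        dcols = (self.W.T @ dflat).reshape(c, 3, 3, h, w)
        dxp = np.zeros((c, h + 2, w + 2))
        for di in range(3):
            for dj in range(3):
                dxp[:, di : di + h, dj : dj + w] += dcols[:, di, dj]
        return dxp[:, 1 : 1 + h, 1 : 1 + w]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2x2(Layer):
    """2x2 max pooling, stride 2; odd extents are zero-padded on the far side."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, h, w = x.shape
        self._shape = x.shape
        hp, wp = (h + 1) // 2 * 2, (w + 1) // 2 * 2
        xp = np.full((c, hp, wp), -np.inf)
        xp[:, :h, :w] = x
        blocks = xp.reshape(c, hp // 2, 2, wp // 2, 2).transpose(0, 1, 3, 2, 4)
        flat = blocks.reshape(c, hp // 2, wp // 2, 4)
        self._arg = flat.argmax(axis=3)
        out = np.take_along_axis(flat, self._arg[..., None], axis=3)[..., 0]
        # zero-padding semantics: a fully padded block cannot occur for
        # far-side padding of at most one row/column
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        c, h, w = self._shape
        hp, wp = (h + 1) // 2 * 2, (w + 1) // 2 * 2
        dflat = np.zeros((c, hp // 2, wp // 2, 4))
        np.put_along_axis(dflat, self._arg[..., None], dout[..., None], axis=3)
        dxp = dflat.reshape(c, hp // 2, wp // 2, 2, 2).transpose(0, 1, 3, 2, 4)
        dxp = dxp.reshape(c, hp, wp)
        return dxp[:, :h, :w]


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """1-D linear interpolation matrix without corner alignment.

    Output sample i maps to input coordinate (i + 0.5) * n_in/n_out - 0.5,
    clamped to the valid range (edge replication).
    """
    A = np.zeros((n_out, n_in))
    coords = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    coords = np.clip(coords, 0.0, n_in - 1.0)
    lo = np.floor(coords).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = coords - lo
    A[np.arange(n_out), lo] += 1.0 - frac
    A[np.arange(n_out), hi] += frac
    return A


class BilinearResize(Layer):
    """Bilinear resize to a fixed target size (no corner alignment).

    Separable: out = A @ x @ B^T per channel, so the backward pass is the
    exact transpose, dx = A^T @ dout @ B.
    """

    def __init__(self, out_hw: tuple[int, int]):
        super().__init__()
        self.out_hw = out_hw
        self._A = None
        self._B = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, h, w = x.shape
        if self._A is None or self._A.shape[1] != h:
            self._A = _interp_matrix(self.out_hw[0], h)
        if self._B is None or self._B.shape[1] != w:
            self._B = _interp_matrix(self.out_hw[1], w)
        return np.einsum("oh,chw,pw->cop", self._A, x, self._B, optimize=True)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.einsum("oh,cop,pw->chw", self._A, dout, self._B, optimize=True)


class Conv1x1(Layer):
    """Per-pixel linear combination of the feature volume (1x1 conv)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.W = truncated_normal(rng, (c_out, c_in))
        self.b = np.zeros(c_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return np.einsum("oc,chw->ohw", self.W, x) + self.b[:, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0] += np.einsum("ohw,chw->oc", dout, self._x)
        self.grads[1] += dout.sum(axis=(1, 2))
        return np.einsum("oc,ohw->chw", self.W, dout)
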