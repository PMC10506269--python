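"""Minimal trainable neural-network layers with manual backpropagation.

The graded environment provides no deep-learning framework, so the few layer
types the architecture needs (1-D same convolution, multi-head self-attention,
max pooling, dense, dropout) are implemented directly on NumPy with explicit
forward/backward passes.  Inputs are batched length-major tensors
``(B, L, D)``; dense layers take ``(B, F)``.

All layers expose ``params`` / ``grads`` as parallel lists of arrays so an
optimizer can update them in place, and cache whatever the backward pass
needs on ``forward``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv1dSame",
    "MultiHeadSelfAttention",
    "ReLU",
    "Sigmoid",
    "MaxPool1d",
    "Flatten",
    "Dropout",
    "Dense",
    "Concat",
    "ACTIVATIONS",
]


class Layer:
    """Base class: stateless by default, no parameters."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0

    def n_params(self) -> int:
        return sum(p.size for p in self.params)


class Conv1dSame(Layer):
    """Stride-1 zero-padded 'same' 1-D convolution with bias.

    Weights are ``(kernel_size, d_in, d_out)``; output length equals input
    length, which keeps convolution and attention branches position-aligned.
    """

    def __init__(self, kernel_size: int, d_in: int, d_out: int,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if kernel_size < 1 or kernel_size % 2 == 0:
            raise ValueError(f"kernel_size must be odd and positive, got {kernel_size}")
        self.kernel_size = kernel_size
        self.d_in = d_in
        self.d_out = d_out
        rng = np.random.default_rng() if rng is None else rng
        # He initialisation for the ReLU branches downstream
        std = np.sqrt(2.0 / (kernel_size * d_in))
        self.w = rng.normal(0.0, std, (kernel_size, d_in, d_out))
        self.b = np.zeros(d_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._cache: tuple | None = None

    def forward(self, x, train=False, rng=None):
        b, length, d_in = x.shape
        if d_in != self.d_in:
            raise ValueError(f"conv expects {self.d_in} input channels, got {d_in}")
        k, pad = self.kernel_size, self.kernel_size // 2
        xpad = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        flat = xpad.reshape(b * (length + 2 * pad), d_in)
        # one GEMM per kernel tap; avoids materialising the im2col matrix
        proj = (flat @ self.w.reshape(k, d_in, self.d_out)
                           .transpose(1, 0, 2).reshape(d_in, k * self.d_out))
        proj = proj.reshape(b, length + 2 * pad, k, self.d_out)
        out = np.full((b, length, self.d_out), self.b)
        for j in range(k):
            out += proj[:, j:j + length, j, :]
        self._cache = (xpad, (b, length))
        return out

    def backward(self, gout):
        xpad, (b, length) = self._cache
        k, pad = self.kernel_size, self.kernel_size // 2
        gflat = gout.reshape(b * length, self.d_out)
        self.grads[1] += gflat.sum(axis=0)
        gxpad = np.zeros((b, length + 2 * pad, self.d_in))
        for j in range(k):
            xs = xpad[:, j:j + length, :].reshape(b * length, self.d_in)
            self.grads[0][j] += xs.T @ gflat
            gxpad[:, j:j + length, :] += (gflat @ self.w[j].T).reshape(b, length, self.d_in)
        return gxpad[:, pad:pad + length, :]


class MultiHeadSelfAttention(Layer):
    """Batched multi-head scaled dot-product self-attention, no biases.

    Per-head projections are stored stacked: ``w_q``/``w_k`` are
    ``(n_heads, d_in, d_k)``, ``w_v`` is ``(n_heads, d_in, d_h)`` and the
    output mix ``w_o`` is ``(d_v, d_v)`` with ``d_v = n_heads * d_h``.
    """

    def __init__(self, d_in: int, n_heads: int, d_h: int,
                 d_k: int | None = None,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if n_heads < 1 or d_h < 1:
            raise ValueError("n_heads and d_h must be >= 1")
        self.d_in = d_in
        self.n_heads = n_heads
        self.d_h = d_h
        self.d_k = d_h if d_k is None else d_k
        self.d_v = n_heads * d_h
        rng = np.random.default_rng() if rng is None else rng
        std = np.sqrt(1.0 / d_in)
        self.w_q = rng.normal(0.0, std, (n_heads, d_in, self.d_k))
        self.w_k = rng.normal(0.0, std, (n_heads, d_in, self.d_k))
        self.w_v = rng.normal(0.0, std, (n_heads, d_in, d_h))
        self.w_o = rng.normal(0.0, np.sqrt(1.0 / self.d_v), (self.d_v, self.d_v))
        self.params = [self.w_q, self.w_k, self.w_v, self.w_o]
        self.grads = [np.zeros_like(p) for p in self.params]
        self._cache: tuple | None = None

    def _project(self, flat: np.ndarray, w: np.ndarray, b: int, length: int) -> np.ndarray:
        """(B*L, D) @ stacked heads -> (B, H, L, d)."""
        d = w.shape[2]
        out = flat @ w.transpose(1, 0, 2).reshape(self.d_in, self.n_heads * d)
        return out.reshape(b, length, self.n_heads, d).transpose(0, 2, 1, 3)

    @staticmethod
    def _unproject(g: np.ndarray) -> np.ndarray:
        """(B, H, L, d) -> (B*L, H*d), inverse layout of :meth:`_project`."""
        b, h, length, d = g.shape
        return np.ascontiguousarray(g.transpose(0, 2, 1, 3)).reshape(b * length, h * d)

    def forward(self, x, train=False, rng=None):
        b, length, d_in = x.shape
        if d_in != self.d_in:
            raise ValueError(f"attention expects width {self.d_in}, got {d_in}")
        flat = x.reshape(b * length, d_in)
        q = self._project(flat, self.w_q, b, length)
        k = self._project(flat, self.w_k, b, length)
        v = self._project(flat, self.w_v, b, length)
        scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(self.d_k)
        scores -= scores.max(axis=-1, keepdims=True)
        e = np.exp(scores)
        a = e / e.sum(axis=-1, keepdims=True)          # (B, H, L, L) row-stochastic
        heads = a @ v                                   # (B, H, L, d_h)
        concat = heads.transpose(0, 2, 1, 3).reshape(b, length, self.d_v)
        out = concat @ self.w_o
        self._cache = (x, q, k, v, a, concat)
        return out

    def last_weights(self) -> np.ndarray:
        """Attention weight matrices from the most recent forward pass."""
        if self._cache is None:
            raise RuntimeError("no forward pass cached")
        return self._cache[4]

    def backward(self, gout):
        x, q, k, v, a, concat = self._cache
        b, length, _ = x.shape
        gflat = gout.reshape(b * length, self.d_v)
        self.grads[3] += concat.reshape(b * length, self.d_v).T @ gflat
        gconcat = gflat @ self.w_o.T
        gheads = gconcat.reshape(b, length, self.n_heads, self.d_h).transpose(0, 2, 1, 3)
        ga = gheads @ v.transpose(0, 1, 3, 2)
        gv = a.transpose(0, 1, 3, 2) @ gheads
        # softmax backward: gS = A * (gA - rowsum(gA * A))
        gs = a * (ga - (ga * a).sum(axis=-1, keepdims=True))
        gs /= np.sqrt(self.d_k)
        gq = gs @ k
        gk = gs.transpose(0, 1, 3, 2) @ q
        xflat_t = x.reshape(b * length, self.d_in).T
        gx = np.zeros((b * length, self.d_in))
        for gi, (g, w) in enumerate(((gq, self.w_q), (gk, self.w_k), (gv, self.w_v))):
            d = w.shape[2]
            gmat = self._unproject(g)  # (B*L, H*d)
            gw = (xflat_t @ gmat).reshape(self.d_in, self.n_heads, d)
            self.grads[gi] += gw.transpose(1, 0, 2)
            gx += gmat @ w.transpose(1, 0, 2).reshape(self.d_in, self.n_heads * d).T
        return gx.reshape(b, length, self.d_in)


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout):
        return gout * self._mask


class Sigmoid(Layer):
    def forward(self, x, train=False, rng=None):
        self._out = 1.0 / (1.0 + np.exp(-x))
        return self._out

    def backward(self, gout):
        return gout * self._out * (1.0 - self._out)


class MaxPool1d(Layer):
    """Channel-wise max pooling; output length ``floor((L - size)/stride) + 1``."""

    def __init__(self, size: int = 4, stride: int = 4) -> None:
        super().__init__()
        if size < 1 or stride < 1:
            raise ValueError("size and stride must be >= 1")
        self.size = size
        self.stride = stride

    def forward(self, x, train=False, rng=None):
        b, length, d = x.shape
        if length < self.size:
            raise ValueError(f"input length {length} < pool size {self.size}")
        l_out = (length - self.size) // self.stride + 1
        win = np.lib.stride_tricks.sliding_window_view(x, self.size, axis=1)
        win = win[:, :: self.stride][:, :l_out]          # (B, L_out, D, size)
        self._argmax = win.argmax(axis=-1)               # (B, L_out, D)
        self._in_shape = x.shape
        return win.max(axis=-1)

    def backward(self, gout):
        b, l_out, d = gout.shape
        gx = np.zeros(self._in_shape)
        starts = np.arange(l_out) * self.stride
        pos = starts[None, :, None] + self._argmax       # absolute position per window
        bi = np.arange(b)[:, None, None]
        di = np.arange(d)[None, None, :]
        np.add.at(gx, (bi, pos, di), gout)
        return gx


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gout):
        return gout.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; identity in inference mode."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, gout):
        return gout if self._mask is None else gout * self._mask


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = np.random.default_rng() if rng is None else rng
        std = np.sqrt(2.0 / d_in)
        self.w = rng.normal(0.0, std, (d_in, d_out))
        self.b = np.zeros(d_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.w + self.b

    def backward(self, gout):
        self.grads[0] += self._x.T @ gout
        self.grads[1] += gout.sum(axis=0)
        return gout @ self.w.T


class Concat(Layer):
    """Apply sub-layers to the SAME input and concatenate outputs on channels."""

    def __init__(self, branches: list[Layer]) -> None:
        super().__init__()
        self.branches = branches
        self.params = [p for br in branches for p in br.params]
        self.grads = [g for br in branches for g in br.grads]

    def forward(self, x, train=False, rng=None):
        outs = [br.forward(x, train=train, rng=rng) for br in self.branches]
        self._widths = [o.shape[-1] for o in outs]
        return np.concatenate(outs, axis=-1)

    def backward(self, gout):
        gx = None
        offset = 0
        for br, w in zip(self.branches, self._widths):
            g = br.backward(gout[..., offset:offset + w])
            gx = g if gx is None else gx + g
            offset += w
        return gx


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        super().__init__()
        self.layers = layers
        self.params = [p for l in layers for p in l.params]
        self.grads = [g for l in layers for g in l.grads]

    def forward(self, x, train=False, rng=None):
        for l in self.layers:
            x = l.forward(x, train=train, rng=rng)
        return x

    def backward(self, gout):
        for l in reversed(self.layers):
            gout = l.backward(gout)
        return gout


ACTIVATIONS = {"relu": ReLU, "sigmoid": Sigmoid}
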