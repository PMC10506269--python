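"""Scaled dot-product self-attention and multi-head concatenation.

This module is the in-memory mathematical core: pure functions over 2-D
``L x D`` feature maps with explicit parameter objects.  Batched, trainable
wrappers live in :mod:`deepcac.nn`.

For a feature map ``X`` (rows are sequence positions) a single head computes

    Head(X) = softmax((X W_Q)(X W_K)^T / sqrt(d_k)) (X W_V)

and multiple heads are concatenated along channels and mixed by ``W_o``.
Projections carry no bias terms, and there is no positional encoding:
positional information enters the network only through convolution branches.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "AttentionHeadParams",
    "MHAParams",
    "softmax_rows",
    "attention_weights",
    "single_head_attention",
    "multi_head_attention",
]


@dataclasses.dataclass(frozen=True)
class AttentionHeadParams:
    """Projection matrices for one attention head.

    ``w_q``/``w_k`` are ``D x d_k`` and ``w_v`` is ``D x d_h`` where ``d_h``
    is the per-head value width (``d_k == d_h`` by default elsewhere).
    """

    w_q: np.ndarray
    w_k: np.ndarray
    w_v: np.ndarray

    def __post_init__(self) -> None:
        for name in ("w_q", "w_k", "w_v"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        if self.w_q.ndim != 2 or self.w_k.ndim != 2 or self.w_v.ndim != 2:
            raise ValueError("head projections must be 2-D matrices")
        if self.w_q.shape != self.w_k.shape:
            raise ValueError(
                f"w_q shape {self.w_q.shape} != w_k shape {self.w_k.shape}"
            )
        if self.w_v.shape[0] != self.w_q.shape[0]:
            raise ValueError(
                f"w_v input width {self.w_v.shape[0]} != w_q input width {self.w_q.shape[0]}"
            )
        if self.d_k < 1:
            raise ValueError("d_k must be >= 1")

    @property
    def d_in(self) -> int:
        return self.w_q.shape[0]

    @property
    def d_k(self) -> int:
        return self.w_q.shape[1]

    @property
    def d_h(self) -> int:
        return self.w_v.shape[1]


@dataclasses.dataclass(frozen=True)
class MHAParams:
    """Per-head projections plus the output mix ``w_o`` (``d_v x d_v``)."""

    heads: tuple[AttentionHeadParams, ...]
    w_o: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "heads", tuple(self.heads))
        object.__setattr__(self, "w_o", np.asarray(self.w_o, dtype=np.float64))
        if not self.heads:
            raise ValueError("need at least one head")
        h0 = self.heads[0]
        for j, h in enumerate(self.heads):
            if (h.d_in, h.d_k, h.d_h) != (h0.d_in, h0.d_k, h0.d_h):
                raise ValueError(
                    f"head {j} geometry {(h.d_in, h.d_k, h.d_h)} differs from "
                    f"head 0 {(h0.d_in, h0.d_k, h0.d_h)}"
                )
        d_v = self.d_v
        if self.w_o.shape != (d_v, d_v):
            raise ValueError(f"w_o must be {d_v} x {d_v}, got {self.w_o.shape}")

    @property
    def n_heads(self) -> int:
        return len(self.heads)

    @property
    def d_in(self) -> int:
        return self.heads[0].d_in

    @property
    def d_v(self) -> int:
        return self.n_heads * self.heads[0].d_h

    @classmethod
    def random(
        cls,
        d_in: int,
        n_heads: int,
        d_h: int,
        d_k: int | None = None,
        rng: np.random.Generator | None = None,
        scale: float = 0.1,
    ) -> "MHAParams":
        """Gaussian-initialised parameters, mainly for tests and examples."""
        rng = np.random.default_rng() if rng is None else rng
        d_k = d_h if d_k is None else d_k
        heads = tuple(
            AttentionHeadParams(
                w_q=rng.normal(0.0, scale, (d_in, d_k)),
                w_k=rng.normal(0.0, scale, (d_in, d_k)),
                w_v=rng.normal(0.0, scale, (d_in, d_h)),
            )
            for _ in range(n_heads)
        )
        d_v = n_heads * d_h
        return cls(heads=heads, w_o=rng.normal(0.0, scale, (d_v, d_v)))


def softmax_rows(m: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max-subtraction for numerical stability."""
    m = np.asarray(m, dtype=np.float64)
    if not np.all(np.isfinite(m)):
        raise ValueError("softmax input contains non-finite entries")
    shifted = m - m.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def _check_width(x: np.ndarray, d_in: int, what: str) -> None:
    if x.shape[-1] != d_in:
        raise ValueError(
            f"{what}: input width {x.shape[-1]} (shape {x.shape}) does not match "
            f"parameter input width {d_in}"
        )


def attention_weights(x: np.ndarray, p: AttentionHeadParams) -> np.ndarray:
    """The ``L x L`` row-stochastic weight matrix of one head."""
    x = np.asarray(x, dtype=np.float64)
    _check_width(x, p.d_in, "attention_weights")
    q = x @ p.w_q
    k = x @ p.w_k
    return softmax_rows(q @ k.T / np.sqrt(p.d_k))


def single_head_attention(x: np.ndarray, p: AttentionHeadParams) -> np.ndarray:
    """One head of scaled dot-product self-attention on an ``L x D`` input."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError(f"expected L x D input, got shape {x.shape}")
    _check_width(x, p.d_in, "single_head_attention")
    return attention_weights(x, p) @ (x @ p.w_v)


def multi_head_attention(x: np.ndarray, p: MHAParams) -> np.ndarray:
    """Concatenate all head outputs along channels and mix with ``w_o``.

    The result already has the target ``L x d_v`` shape; the final reshape is
    a shape assertion only.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError(f"expected L x D input, got shape {x.shape}")
    _check_width(x, p.d_in, "multi_head_attention")
    concat = np.concatenate([single_head_attention(x, h) for h in p.heads], axis=1)
    out = concat @ p.w_o
    assert out.shape == (x.shape[0], p.d_v)
    return out
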