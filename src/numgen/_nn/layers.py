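"""Minimal layer library with explicit forward/backward passes.

Every layer caches what its backward pass needs on ``forward`` and returns the
input gradient from ``backward`` while accumulating parameter gradients in
place.  The library is deliberately small: dense maps, layer normalisation,
multi-head scaled dot-product self-attention with an additive mask, a
position-wise feed-forward block and the post-norm encoder block that chains
them with residual connections.
"""

from __future__ import annotations

from typing import Iterator, Optional

import numpy as np

from .functional import softmax


class Param:
    """A trainable array together with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def shape(self):
        return self.value.shape


class Layer:
    def params(self) -> Iterator[Param]:
        for v in vars(self).values():
            if isinstance(v, Param):
                yield v
            elif isinstance(v, Layer):
                yield from v.params()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Layer):
                        yield from item.params()

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 dtype=np.float32, name: str = "dense"):
        scale = 1.0 / np.sqrt(d_in)
        self.W = Param(rng.uniform(-scale, scale, (d_in, d_out)).astype(dtype),
                       f"{name}.W")
        self.b = Param(np.zeros(d_out, dtype=dtype), f"{name}.b")
        self._x: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        x = self._x
        x2 = x.reshape(-1, x.shape[-1])
        g2 = g.reshape(-1, g.shape[-1])
        self.W.grad += x2.T @ g2
        self.b.grad += g2.sum(axis=0)
        return g @ self.W.value.T


class LayerNorm(Layer):
    def __init__(self, d: int, dtype=np.float32, eps: float = 1e-5,
                 name: str = "ln"):
        self.gamma = Param(np.ones(d, dtype=dtype), f"{name}.gamma")
        self.beta = Param(np.zeros(d, dtype=dtype), f"{name}.beta")
        self.eps = eps

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv_std
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._xhat, self._inv_std
        gx = g * self.gamma.value
        self.gamma.grad += np.sum(g * xhat, axis=tuple(range(g.ndim - 1)))
        self.beta.grad += np.sum(g, axis=tuple(range(g.ndim - 1)))
        m = gx.mean(axis=-1, keepdims=True)
        mx = (gx * xhat).mean(axis=-1, keepdims=True)
        return inv_std * (gx - m - xhat * mx)


class Dropout(Layer):
    """Inverted dropout; identity when ``train`` is False or rate is 0."""

    def __init__(self, rate: float):
        self.rate = float(rate)
        self._mask: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray, train: bool,
                rng: Optional[np.random.Generator]) -> np.ndarray:
        if not train or self.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g if self._mask is None else g * self._mask


class MultiHeadSelfAttention(Layer):
    """Masked multi-head scaled dot-product self-attention.

    ``mask`` is a boolean (q, q) permission matrix: ``mask[i, j]`` True means
    query position i may attend to key position j.  Disallowed scores receive
    a large negative additive bias before the softmax.
    """

    NEG = -1e9

    def __init__(self, d: int, n_heads: int, rng: np.random.Generator,
                 dtype=np.float32, name: str = "mha"):
        if d % n_heads:
            raise ValueError(f"d={d} not divisible by n_heads={n_heads}")
        self.n_heads = n_heads
        self.d_head = d // n_heads
        self.wq = Dense(d, d, rng, dtype, f"{name}.wq")
        self.wk = Dense(d, d, rng, dtype, f"{name}.wk")
        self.wv = Dense(d, d, rng, dtype, f"{name}.wv")
        self.wo = Dense(d, d, rng, dtype, f"{name}.wo")

    def _split(self, x: np.ndarray) -> np.ndarray:
        b, q, d = x.shape
        return x.reshape(b, q, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        b, h, q, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(b, q, h * dh)

    def _fold(self, x: np.ndarray) -> np.ndarray:
        """(b, q, d) -> contiguous (b * h, q, d_head)."""
        b, q, d = x.shape
        return np.ascontiguousarray(
            x.reshape(b, q, self.n_heads, self.d_head).transpose(0, 2, 1, 3)
        ).reshape(b * self.n_heads, q, self.d_head)

    def _unfold(self, x: np.ndarray, b: int) -> np.ndarray:
        q = x.shape[1]
        return x.reshape(b, self.n_heads, q, self.d_head) \
            .transpose(0, 2, 1, 3).reshape(b, q, self.n_heads * self.d_head)

    @staticmethod
    def _is_causal(mask: np.ndarray) -> bool:
        q = mask.shape[0]
        return mask.shape == (q, q) and bool(
            np.array_equal(mask, np.tril(np.ones((q, q), dtype=bool))))

    def forward(self, x: np.ndarray, mask: np.ndarray) -> np.ndarray:
        from .fastattn import softmax_causal

        b = x.shape[0]
        # fold the scale into Q so the big score array needs no extra pass
        Q = self._fold(self.wq.forward(x)) * (1.0 / float(np.sqrt(self.d_head)))
        K = self._fold(self.wk.forward(x))
        V = self._fold(self.wv.forward(x))
        scores = Q @ K.transpose(0, 2, 1)
        causal = self._is_causal(mask)
        if causal:
            A = softmax_causal(scores)
        else:
            scores = np.where(mask, scores, self.NEG)
            A = softmax(scores, axis=-1)
        ctx = A @ V
        self._cache = (Q, K, V, A, b, causal)
        return self.wo.forward(self._unfold(ctx, b))

    def backward(self, g: np.ndarray) -> np.ndarray:
        from .fastattn import softmax_causal_grad

        Q, K, V, A, b, causal = self._cache
        d_ctx = self._fold(self.wo.backward(g))
        dA = d_ctx @ V.transpose(0, 2, 1)
        dV = A.transpose(0, 2, 1) @ d_ctx
        # masked entries have A == 0 hence zero gradient
        if causal:
            d_scores = softmax_causal_grad(A, dA)
        else:
            d_scores = A * (dA - np.sum(dA * A, axis=-1, keepdims=True))
        dQ = (d_scores @ K) * (1.0 / float(np.sqrt(self.d_head)))
        dK = d_scores.transpose(0, 2, 1) @ Q
        gx = self.wq.backward(self._unfold(dQ, b))
        gx += self.wk.backward(self._unfold(dK, b))
        gx += self.wv.backward(self._unfold(dV, b))
        return gx


class FeedForward(Layer):
    """Position-wise two-layer ReLU network."""

    def __init__(self, d: int, d_ff: int, rng: np.random.Generator,
                 dtype=np.float32, name: str = "ff"):
        self.fc1 = Dense(d, d_ff, rng, dtype, f"{name}.fc1")
        self.fc2 = Dense(d_ff, d, rng, dtype, f"{name}.fc2")

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.fc1.forward(x)
        self._pre = h
        return self.fc2.forward(np.maximum(h, 0.0))

    def backward(self, g: np.ndarray) -> np.ndarray:
        gh = self.fc2.backward(g)
        gh = gh * (self._pre > 0)
        return self.fc1.backward(gh)


class EncoderBlock(Layer):
    """Post-norm transformer encoder block.

    ``A = norm(H + mha(H))`` followed by ``H' = norm(A + fc(A))`` — the
    normalisation is applied after each residual addition, and the same
    attention-permission mask is reused at every block.
    """

    def __init__(self, d: int, n_heads: int, d_ff: int,
                 rng: np.random.Generator, dropout: float = 0.0,
                 dtype=np.float32, name: str = "block"):
        self.mha = MultiHeadSelfAttention(d, n_heads, rng, dtype, f"{name}.mha")
        self.ln1 = LayerNorm(d, dtype, name=f"{name}.ln1")
        self.ff = FeedForward(d, d_ff, rng, dtype, f"{name}.ff")
        self.ln2 = LayerNorm(d, dtype, name=f"{name}.ln2")
        self.drop1 = Dropout(dropout)
        self.drop2 = Dropout(dropout)

    def forward(self, x: np.ndarray, mask: np.ndarray, train: bool = False,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
        a = self.ln1.forward(x + self.drop1.forward(
            self.mha.forward(x, mask), train, rng))
        return self.ln2.forward(a + self.drop2.forward(
            self.ff.forward(a), train, rng))

    def backward(self, g: np.ndarray) -> np.ndarray:
        ga = self.ln2.backward(g)
        ga = ga + self.ff.backward(self.drop2.backward(ga))
        gx = self.ln1.backward(ga)
        return gx + self.mha.backward(self.drop1.backward(gx))
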