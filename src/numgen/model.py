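"""Encoder-only pixel-autoregressive transformer conditioned on numerosity.

The network maps a conditioning seed (the *Start of String*, one learned
d-vector per trained numerosity) followed by an embedded pixel prefix to one
conditional PMF over intensity levels per sequence position:

* position 0 holds ``s + WE[0]`` where ``s`` is the seed,
* position i >= 1 holds ``Wx[x_i] + WE[i]`` for the (i)th scanned intensity,
* a causal attention mask lets position i attend only to positions 0..i, so
  row i of the output is ``q(x_{i+1} | x_1..x_i, n)`` and the chain rule
  factorisation of the image likelihood is enforced architecturally.

Intensity, seed and positional embeddings are all learned tables (``Wx``,
``Ws``, ``WE``); there are no fixed sinusoids, so the model carries no prior
notion of gray-level distance, number order or pixel adjacency.  The encoder
is a stack of post-norm blocks — masked multi-head scaled dot-product
attention and a position-wise feed-forward net, each wrapped in residual
addition followed by layer normalisation — topped by a linear map to
intensity logits and a per-row softmax.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import asdict, dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.base import BaseEstimator

from ._nn import Dense, EncoderBlock, Param, softmax

__all__ = ["ModelConfig", "ParameterTables", "TransformerCore",
           "PixelTransformer", "causal_mask", "embed_sequence",
           "encoder_forward", "output_pmfs", "TINY_CONFIG"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyper-parameters.

    ``n_layers`` counts encoder blocks (each contributes an attention and a
    feed-forward sub-layer); ``vocab_size`` is the number of categorical
    intensity levels p; ``n_pixels`` the flattened image length r, which the
    learned positional table pins down as the maximum resolution.
    """

    n_layers: int = 4
    d_model: int = 128
    n_heads: int = 8
    vocab_size: int = 256
    n_pixels: int = 1024
    numerosities: Tuple[int, ...] = tuple(range(1, 9))
    ff_width: int = 512
    dropout: float = 0.1

    def __post_init__(self):
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if min(self.n_layers, self.d_model, self.n_heads, self.vocab_size,
               self.n_pixels, self.ff_width) < 0 or self.vocab_size < 2:
            raise ValueError("invalid model configuration")
        if len(self.numerosities) == 0:
            raise ValueError("at least one conditioning numerosity required")
        object.__setattr__(self, "numerosities",
                           tuple(sorted(int(n) for n in self.numerosities)))


#: two-block, 32-wide preset used for the desk-scale experiments and tests.
TINY_CONFIG = ModelConfig(n_layers=2, d_model=32, n_heads=4, vocab_size=2,
                          n_pixels=144, numerosities=(1, 2, 3), ff_width=128,
                          dropout=0.0)


def causal_mask(q: int) -> np.ndarray:
    """Boolean (q, q) permission matrix: entry (i, j) allows query i to
    attend to key j iff j <= i.  The seed (position 0) attends only to
    itself; the same matrix is reused at every encoder block."""
    if q < 1:
        raise ValueError("sequence length must be >= 1")
    return np.tril(np.ones((q, q), dtype=bool))


class TransformerCore:
    """Parameter container plus explicit forward/backward passes."""

    def __init__(self, config: ModelConfig, seed: int = 0,
                 dtype=np.float32):
        self.config = config
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        d = config.d_model

        def trunc_normal(shape, std=0.02):
            x = rng.normal(0.0, std, size=shape)
            np.clip(x, -2 * std, 2 * std, out=x)
            return x.astype(self.dtype)

        self.Wx = Param(trunc_normal((config.vocab_size, d)), "Wx")
        self.Ws = Param(trunc_normal((len(config.numerosities), d)), "Ws")
        self.WE = Param(trunc_normal((config.n_pixels, d)), "WE")
        self.blocks: List[EncoderBlock] = [
            EncoderBlock(d, config.n_heads, config.ff_width, rng,
                         config.dropout, self.dtype, name=f"block{i}")
            for i in range(config.n_layers)]
        self.head = Dense(d, config.vocab_size, rng, self.dtype, "head")

    # -- parameter access ---------------------------------------------------

    def params(self) -> List[Param]:
        out = [self.Wx, self.Ws, self.WE]
        for blk in self.blocks:
            out.extend(blk.params())
        out.extend(self.head.params())
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def seed_vector(self, n: int) -> np.ndarray:
        """Copy of the trained seed (row of Ws) for numerosity ``n``."""
        try:
            idx = self.config.numerosities.index(int(n))
        except ValueError:
            raise KeyError(
                f"numerosity {n} not in trained set "
                f"{self.config.numerosities}") from None
        return self.Ws.value[idx].copy()

    # -- forward / backward -------------------------------------------------

    def embed(self, prefix: np.ndarray, sos: np.ndarray) -> np.ndarray:
        """Input activations H0 for a batch: seed token then embedded prefix."""
        prefix = np.asarray(prefix)
        b, qm1 = prefix.shape
        if qm1 > self.config.n_pixels - 1:
            raise ValueError(
                f"prefix length {qm1} exceeds r-1 = {self.config.n_pixels - 1}")
        if qm1 and prefix.max() >= self.config.vocab_size:
            raise ValueError("intensity index out of range")
        H0 = np.empty((b, qm1 + 1, self.config.d_model), dtype=self.dtype)
        H0[:, 0] = sos + self.WE.value[0]
        if qm1:
            H0[:, 1:] = self.Wx.value[prefix] + self.WE.value[1:qm1 + 1]
        return H0

    def forward(self, prefix: np.ndarray, sos: np.ndarray,
                sos_index: Optional[np.ndarray] = None, train: bool = False,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
        """Teacher-forced pass: logits of shape (batch, q, p).

        ``sos`` is a (batch, d) array of seed vectors; ``sos_index`` carries
        the Ws row of each seed when the gradient should flow into the seed
        table (None for externally supplied probe seeds).
        """
        prefix = np.asarray(prefix, dtype=np.int64)
        H = self.embed(prefix, np.asarray(sos, dtype=self.dtype))
        mask = causal_mask(H.shape[1])
        self._cache = (prefix, sos_index, H.shape)
        for blk in self.blocks:
            H = blk.forward(H, mask, train=train, rng=rng)
        return self.head.forward(H)

    def backward(self, dlogits: np.ndarray) -> None:
        prefix, sos_index, shape = self._cache
        g = self.head.backward(dlogits)
        for blk in reversed(self.blocks):
            g = blk.backward(g)
        b, q, d = shape
        if sos_index is not None:
            np.add.at(self.Ws.grad, sos_index, g[:, 0])
        self.WE.grad[0] += g[:, 0].sum(axis=0)
        if q > 1:
            flat = g[:, 1:].reshape(-1, d)
            np.add.at(self.Wx.grad, prefix.ravel(), flat)
            self.WE.grad[1:q] += g[:, 1:].sum(axis=0)

    def pmfs(self, prefix: np.ndarray, sos: np.ndarray) -> np.ndarray:
        """Row-stochastic conditional PMF matrix (batch, q, p)."""
        return softmax(self.forward(prefix, sos), axis=-1)

    # -- incremental decoding ----------------------------------------------

    def start_cache(self, batch: int) -> "_KVCache":
        return _KVCache(self, batch)

    # -- serialization ------------------------------------------------------

    FORMAT = "numgen-checkpoint-1"

    def save(self, path) -> None:
        header = {"format": self.FORMAT, "config": asdict(self.config),
                  "dtype": self.dtype.name}
        buf = io.BytesIO()
        np.savez(buf, **{f"param_{i:04d}": p.value
                         for i, p in enumerate(self.params())})
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("header.json", json.dumps(header))
            zf.writestr("params.npz", buf.getvalue())

    @classmethod
    def load(cls, path) -> "TransformerCore":
        with zipfile.ZipFile(path) as zf:
            header = json.loads(zf.read("header.json"))
            if header["format"] != cls.FORMAT:
                raise ValueError(f"unknown checkpoint format {header['format']}")
            data = np.load(io.BytesIO(zf.read("params.npz")))
            cfg = header["config"]
            cfg["numerosities"] = tuple(cfg["numerosities"])
            core = cls(ModelConfig(**cfg), dtype=np.dtype(header["dtype"]))
            for i, p in enumerate(core.params()):
                val = data[f"param_{i:04d}"]
                if val.shape != p.value.shape:
                    raise ValueError("checkpoint shape mismatch")
                p.value[...] = val
        return core

    def state_copy(self) -> List[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def load_state(self, state: List[np.ndarray]) -> None:
        for p, v in zip(self.params(), state):
            p.value[...] = v


class _KVCache:
    """Per-layer key/value cache for O(q) incremental decoding.

    Feeding tokens one by one through :meth:`step` reproduces the rows of the
    full teacher-forced pass exactly (prefix consistency), because each new
    position only ever attends to itself and cached earlier positions.
    """

    def __init__(self, core: TransformerCore, batch: int):
        cfg = core.config
        self.core = core
        self.t = 0
        dh = cfg.d_model // cfg.n_heads
        self.K = [np.empty((batch, cfg.n_heads, cfg.n_pixels, dh),
                           dtype=core.dtype) for _ in core.blocks]
        self.V = [np.empty_like(k) for k in self.K]

    def step(self, token: np.ndarray) -> np.ndarray:
        """Advance one position; ``token`` is (batch, d); returns logits
        (batch, p) for the next intensity."""
        core, t = self.core, self.t
        h = token[:, None, :].astype(core.dtype)
        for l, blk in enumerate(core.blocks):
            mha = blk.mha
            qh = mha._split(mha.wq.forward(h))
            kh = mha._split(mha.wk.forward(h))
            vh = mha._split(mha.wv.forward(h))
            self.K[l][:, :, t:t + 1] = kh
            self.V[l][:, :, t:t + 1] = vh
            keys = self.K[l][:, :, :t + 1]
            vals = self.V[l][:, :, :t + 1]
            scores = qh @ keys.transpose(0, 1, 3, 2) / float(np.sqrt(mha.d_head))
            ctx = softmax(scores, axis=-1) @ vals
            a = blk.ln1.forward(h + mha.wo.forward(mha._merge(ctx)))
            h = blk.ln2.forward(a + blk.ff.forward(a))
        self.t += 1
        return core.head.forward(h)[:, 0]


class ParameterTables:
    """Read-only view of the learned tables of a :class:`TransformerCore`."""

    def __init__(self, core: TransformerCore):
        self._core = core

    @property
    def Wx(self) -> np.ndarray:
        return self._core.Wx.value

    @property
    def Ws(self) -> np.ndarray:
        return self._core.Ws.value

    @property
    def WE(self) -> np.ndarray:
        return self._core.WE.value

    @property
    def numerosities(self) -> Tuple[int, ...]:
        return self._core.config.numerosities

    def row_index(self, n: int) -> int:
        try:
            return self.numerosities.index(int(n))
        except ValueError:
            raise KeyError(f"numerosity {n} not in trained set "
                           f"{self.numerosities}") from None


# ---------------------------------------------------------------------------
# functional surface used by the probe tasks and the tests


def embed_sequence(prefix: Sequence[int],
                   sos: Union[int, np.ndarray],
                   core: TransformerCore) -> np.ndarray:
    """H0 for a single sequence: row 0 is ``seed + WE[0]``, row i >= 1 is
    ``Wx[prefix[i-1]] + WE[i]``.  ``sos`` is either a trained numerosity
    (row of Ws) or an arbitrary externally supplied d-vector, as required by
    the interpolation/extrapolation/PCA probes."""
    if np.isscalar(sos):
        vec = core.seed_vector(int(sos))
    else:
        vec = np.asarray(sos, dtype=core.dtype)
        if vec.shape != (core.config.d_model,):
            raise ValueError(f"seed vector must have dimension "
                            f"{core.config.d_model}")
    prefix = np.asarray(prefix, dtype=np.int64).reshape(1, -1)
    return core.embed(prefix, vec[None])[0]


def encoder_forward(H0: np.ndarray, mask: np.ndarray,
                    core: TransformerCore) -> np.ndarray:
    """Run the encoder stack (inference mode) on a single (q, d) input."""
    H = np.asarray(H0, dtype=core.dtype)[None]
    if H.shape[2] != core.config.d_model or mask.shape != (H.shape[1],) * 2:
        raise ValueError("shape mismatch between H0, mask and model config")
    for blk in core.blocks:
        H = blk.forward(H, mask, train=False)
    return H[0]


def output_pmfs(HL: np.ndarray, core: TransformerCore,
                return_logits: bool = False):
    """Per-row conditional PMFs from final activations (q, d)."""
    logits = core.head.forward(np.asarray(HL, dtype=core.dtype))
    P = softmax(logits, axis=-1)
    return (P, logits) if return_logits else P


# ---------------------------------------------------------------------------
# estimator


class PixelTransformer(BaseEstimator):
    """Conditional pixel-autoregressive density estimator.

    scikit-learn style estimator: ``fit(X, y)`` consumes images ``X`` of
    shape (m, H, W) with integer intensities and numerosity labels ``y``,
    minimising the autoregressive negative log-likelihood with teacher
    forcing.  After fitting, ``tables_`` exposes the learned embedding
    matrices, ``sample`` draws new images and ``nll`` scores held-out data.

    Parameters mirror :class:`ModelConfig` plus the optimisation settings
    (Adam with early stopping on validation NLL).
    """

    def __init__(self, n_layers: int = 4, d_model: int = 128,
                 n_heads: int = 8, vocab_size: int = 256,
                 frame_shape: Tuple[int, int] = (32, 32),
                 numerosities: Sequence[int] = tuple(range(1, 9)),
                 ff_width: int = 512, dropout: float = 0.1,
                 learning_rate: float = 3e-4, batch_size: int = 64,
                 epochs: int = 50, patience: int = 10,
                 seed: int = 0, dtype: str = "float32",
                 validation_fraction: float = 0.1):
        self.n_layers = n_layers
        self.d_model = d_model
        self.n_heads = n_heads
        self.vocab_size = vocab_size
        self.frame_shape = frame_shape
        self.numerosities = numerosities
        self.ff_width = ff_width
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.patience = patience
        self.seed = seed
        self.dtype = dtype
        self.validation_fraction = validation_fraction

    # fit lives in numgen.training (same loop serves the module-level
    # train() entry point); imported lazily to keep the layering acyclic.
    def fit(self, X, y, X_val=None, y_val=None):
        from .training import TrainConfig, fit_estimator
        cfg = TrainConfig(learning_rate=self.learning_rate,
                          batch_size=self.batch_size, epochs=self.epochs,
                          patience=self.patience, seed=self.seed)
        fit_estimator(self, X, y, cfg, X_val=X_val, y_val=y_val)
        return self

    def _build_core(self) -> TransformerCore:
        h, w = self.frame_shape
        config = ModelConfig(n_layers=self.n_layers, d_model=self.d_model,
                             n_heads=self.n_heads, vocab_size=self.vocab_size,
                             n_pixels=h * w,
                             numerosities=tuple(self.numerosities),
                             ff_width=self.ff_width, dropout=self.dropout)
        return TransformerCore(config, seed=self.seed,
                               dtype=np.dtype(self.dtype))

    # -- fitted-surface helpers --------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "core_"):
            raise RuntimeError("estimator is not fitted")

    @property
    def tables_(self) -> ParameterTables:
        self._check_fitted()
        return ParameterTables(self.core_)

    def nll(self, X, y, per_pixel: bool = True) -> float:
        """Held-out negative log-likelihood in nats (dropout disabled)."""
        from .training import evaluate_nll
        self._check_fitted()
        return evaluate_nll(self.core_, np.asarray(X), np.asarray(y),
                            per_pixel=per_pixel,
                            batch_size=self.batch_size)

    def score(self, X, y) -> float:
        """Mean log-likelihood per pixel (higher is better)."""
        return -self.nll(X, y, per_pixel=True)

    def sample(self, sos, count: int = 64, seed: int = 0,
               incremental: bool = True) -> np.ndarray:
        from .generation import spontaneous_generate
        from .generation import SoSVector
        self._check_fitted()
        if np.isscalar(sos):
            from .generation import sos_trained
            sos = sos_trained(self.tables_, int(sos))
        elif not isinstance(sos, SoSVector):
            sos = SoSVector(np.asarray(sos), ("external",))
        batch = spontaneous_generate(self, sos, count=count,
                                     rng=np.random.default_rng(seed),
                                     incremental=incremental)
        return batch.images

    def save(self, path) -> None:
        self._check_fitted()
        self.core_.save(path)

    @classmethod
    def from_checkpoint(cls, path) -> "PixelTransformer":
        core = TransformerCore.load(path)
        cfg = core.config
        # frame shape is recovered as a square when possible
        side = int(round(np.sqrt(cfg.n_pixels)))
        shape = (side, cfg.n_pixels // side) if side * side == cfg.n_pixels \
            else (1, cfg.n_pixels)
        est = cls(n_layers=cfg.n_layers, d_model=cfg.d_model,
                  n_heads=cfg.n_heads, vocab_size=cfg.vocab_size,
                  frame_shape=shape, numerosities=cfg.numerosities,
                  ff_width=cfg.ff_width, dropout=cfg.dropout)
        est.core_ = core
        est.history_ = None
        return est
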