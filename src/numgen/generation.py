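"""Image generation and the four conditioning-seed probes.

Two decoding regimes are implemented and deliberately kept separate:

* **conditional (teacher-forced) generation** — every pixel is the argmax of
  the PMF conditioned on the *true* preceding pixels; one forward pass over
  the whole image suffices.  This is a learning monitor, not a sampler.
* **spontaneous generation** — each pixel is *sampled* from the PMF
  conditioned on the previously *sampled* pixels, starting from the seed
  alone; one image needs r sequential decoding steps.

The conditioning seed is either a trained numerosity embedding (a row of Ws)
or a vector manufactured from the embedding space: the midpoint of the two
neighbouring numerosities (interpolation), the largest embedding pushed along
the attribute vector ``w_max - w_secondmax`` (extrapolation), or a row
reconstructed from its top principal components (reduced seed).  Sampling is
plain categorical sampling at temperature 1 — no truncation heuristics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional, Tuple, Union

import numpy as np

from ._nn import softmax
from ._pca import fit_pca
from .model import ParameterTables, PixelTransformer

__all__ = ["SoSVector", "SampleBatch", "conditional_generate",
           "spontaneous_generate", "sos_trained", "sos_interpolated",
           "sos_extrapolated", "sos_pca_reduced"]


@dataclass
class SoSVector:
    """A d-dimensional conditioning seed plus its provenance tag."""

    values: np.ndarray
    provenance: Tuple = ("external",)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("seed must be a flat d-vector")


@dataclass
class SampleBatch:
    """Spontaneously generated frames for one seed."""

    images: np.ndarray           # (count, H, W) categorical intensities
    sos: SoSVector
    seed: Optional[int] = None
    draw_log: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.images)


# ---------------------------------------------------------------------------
# seed construction


def sos_trained(tables: ParameterTables, n: int) -> SoSVector:
    """The learned seed for a trained numerosity (copy; mutating the result
    leaves Ws untouched)."""
    row = tables.row_index(n)
    return SoSVector(tables.Ws[row].copy(), ("trained", int(n)))


def sos_interpolated(tables: ParameterTables, n: int) -> SoSVector:
    """Midpoint of the seeds of the two neighbouring numerosities,
    ``(w_{n-1} + w_{n+1}) / 2`` — the probe for numerosities inside the
    training interval but absent from the training set."""
    nums = tables.numerosities
    if int(n) in nums:
        warnings.warn(f"numerosity {n} is in the trained set; interpolation "
                      "is intended for held-out numerosities", stacklevel=2)
    for nb in (n - 1, n + 1):
        if nb not in nums:
            raise KeyError(f"neighbour numerosity {nb} not in trained set "
                           f"{nums}")
    lo = tables.Ws[tables.row_index(n - 1)]
    hi = tables.Ws[tables.row_index(n + 1)]
    return SoSVector((lo + hi) / 2.0, ("interpolated", int(n)))


def sos_extrapolated(tables: ParameterTables, alpha: float) -> SoSVector:
    """Seed beyond the training range: ``w_max + alpha * (w_max - w_2nd)``.

    The difference of the two largest trained seeds is the attribute vector —
    the direction along which the largest numerosities grow; ``alpha > 0``
    scales the step (alpha = 0 degenerates to the largest trained seed).
    """
    nums = tables.numerosities
    if len(nums) < 2:
        raise ValueError("extrapolation needs at least two trained "
                         "numerosities")
    w_max = tables.Ws[tables.row_index(nums[-1])]
    w_2nd = tables.Ws[tables.row_index(nums[-2])]
    a = w_max - w_2nd
    return SoSVector(w_max + float(alpha) * a,
                     ("extrapolated", float(alpha)))


def sos_pca_reduced(tables: ParameterTables, k: int, n: int) -> SoSVector:
    """Seed for numerosity ``n`` reconstructed from the top-``k`` principal
    components of the (centered) seed matrix, typically k in {1, 2}."""
    nums = tables.numerosities
    basis = fit_pca(tables.Ws)
    if not 1 <= k <= len(nums) - 1:
        raise ValueError(f"k must be in [1, {len(nums) - 1}]")
    row = tables.row_index(n)
    return SoSVector(basis.reconstruct(row, k), ("pca_reduced", int(k),
                                                 int(n)))


# ---------------------------------------------------------------------------
# decoding


def _categorical_draw(pmf: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One draw per row of a row-stochastic matrix, inverse-CDF style."""
    u = rng.random(pmf.shape[0])
    cum = np.cumsum(pmf, axis=1)
    idx = (u[:, None] > cum).sum(axis=1)
    return np.minimum(idx, pmf.shape[1] - 1)


def conditional_generate(model: PixelTransformer, x: np.ndarray,
                         n: int) -> Tuple[np.ndarray, float]:
    """Teacher-forced greedy reconstruction of a ground-truth image.

    Pixel i is the argmax of the PMF conditioned on the *true* pixels before
    it; returns the rebuilt frame and the fraction of pixels on which the
    argmax agrees with the ground truth.  Used only to monitor learning —
    one-step-ahead prediction is far easier than free-running generation.
    """
    model._check_fitted()
    core = model.core_
    x = np.asarray(x)
    seq = x.reshape(1, -1).astype(np.int64)
    if seq.shape[1] != core.config.n_pixels:
        raise ValueError("image size does not match the model")
    sos = core.seed_vector(int(n))  # raises KeyError for untrained n
    logits = core.forward(seq[:, :-1], sos[None])
    pred = logits.argmax(axis=-1)[0]
    agreement = float(np.mean(pred == seq[0]))
    return pred.reshape(x.shape).astype(x.dtype), agreement


def spontaneous_generate(model: PixelTransformer, sos: SoSVector,
                         count: int = 64,
                         rng: Optional[np.random.Generator] = None,
                         incremental: bool = True) -> SampleBatch:
    """Sample ``count`` images pixel-by-pixel from a conditioning seed.

    The first decoding step sees the seed alone; every subsequent pixel is
    drawn from the categorical PMF given the seed and the sampled prefix.
    ``incremental=False`` recomputes the full prefix pass at every step
    (identical output for the same generator state; kept as the reference
    path for the cached decoder).
    """
    model._check_fitted()
    core = model.core_
    if sos.values.shape != (core.config.d_model,):
        raise ValueError(f"seed dimension {sos.values.shape} does not match "
                         f"d={core.config.d_model}")
    rng = rng if rng is not None else np.random.default_rng()
    state = rng.bit_generator.state
    r = core.config.n_pixels
    vec = np.repeat(sos.values[None].astype(core.dtype), count, axis=0)
    samples = np.empty((count, r), dtype=np.int64)
    if incremental:
        cache = core.start_cache(count)
        token = vec + core.WE.value[0]
        for i in range(r):
            logits = cache.step(token)
            samples[:, i] = _categorical_draw(softmax(logits, axis=-1), rng)
            if i + 1 < r:
                token = core.Wx.value[samples[:, i]] + core.WE.value[i + 1]
    else:
        for i in range(r):
            logits = core.forward(samples[:, :i], vec)
            samples[:, i] = _categorical_draw(
                softmax(logits[:, -1], axis=-1), rng)
    h, w = model.frame_shape
    dtype = np.uint8 if core.config.vocab_size <= 256 else np.uint16
    images = samples.reshape(count, h, w).astype(dtype)
    return SampleBatch(images=images, sos=sos,
                       draw_log={"bit_generator_state": state,
                                 "incremental": incremental})
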