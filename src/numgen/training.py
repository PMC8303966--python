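"""Teacher-forced maximum-likelihood training of the pixel transformer.

The objective is the autoregressive negative log-likelihood: for an image
``x`` of r pixels with numerosity n, the loss is the sum over positions of
``-log q(x_i | x_1..x_{i-1}, n)`` — exactly the categorical cross-entropy of
the model logits against the shifted pixel sequence.  The optimiser sees the
mean over pixels and batch (stable step sizes); multiplying by r recovers the
per-image sum and both are reported in the history.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, List, Optional, Sequence

import numpy as np
import pandas as pd

from ._nn import Adam, cross_entropy, cross_entropy_grad

if TYPE_CHECKING:  # pragma: no cover
    from .model import PixelTransformer, TransformerCore
    from .stimuli import DatasetBundle

__all__ = ["TrainConfig", "TrainRecord", "nll_loss", "train",
           "fit_estimator", "evaluate_nll", "loss_vs_train_size"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings, recorded verbatim into the run manifest."""

    optimizer: str = "adam"
    learning_rate: float = 3e-4
    batch_size: int = 64
    epochs: int = 50
    patience: int = 10
    seed: int = 0
    device: str = "cpu"  # hint only; the numpy engine is CPU-bound

    def __post_init__(self):
        if self.batch_size <= 0 or self.epochs < 0 or self.patience < 0:
            raise ValueError("budgets must be positive")
        if self.optimizer != "adam":
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class TrainRecord:
    """Per-epoch loss trace plus the best-checkpoint bookkeeping."""

    history: pd.DataFrame
    best_epoch: int
    best_val_nll: float  # nats per pixel, dropout disabled
    wall_time_s: float
    config: TrainConfig = field(default_factory=TrainConfig)


def nll_loss(logits: np.ndarray, targets: np.ndarray,
             reduction: str = "mean") -> float:
    """Negative log-likelihood of integer targets under categorical logits.

    ``reduction="sum"`` gives the per-sequence inner sum of the
    autoregressive NLL; ``"mean"`` divides by the number of positions.
    """
    logits = np.asarray(logits)
    targets = np.asarray(targets)
    if logits.shape[:-1] != targets.shape:
        raise ValueError(f"logits leading shape {logits.shape[:-1]} does not "
                         f"match targets shape {targets.shape}")
    if targets.size and targets.max() >= logits.shape[-1]:
        raise ValueError("target intensity outside vocabulary")
    return cross_entropy(logits, targets, reduction=reduction)


def _label_indices(y: np.ndarray, numerosities: Sequence[int]) -> np.ndarray:
    lookup = {n: i for i, n in enumerate(numerosities)}
    try:
        return np.array([lookup[int(v)] for v in y], dtype=np.int64)
    except KeyError as err:
        raise ValueError(f"label {err.args[0]} outside the model's "
                         f"numerosity set {tuple(numerosities)}") from None


def evaluate_nll(core: "TransformerCore", X: np.ndarray, y: np.ndarray,
                 per_pixel: bool = True, batch_size: int = 64) -> float:
    """Mean NLL over a split (nats per pixel, or per image), dropout off."""
    m = len(X)
    r = core.config.n_pixels
    seq = X.reshape(m, r)
    idx = _label_indices(y, core.config.numerosities)
    total = 0.0
    for lo in range(0, m, batch_size):
        sl = slice(lo, lo + batch_size)
        logits = core.forward(seq[sl, :-1], core.Ws.value[idx[sl]],
                              train=False)
        total += nll_loss(logits, seq[sl], reduction="sum")
    per_pix = total / (m * r)
    return per_pix if per_pixel else per_pix * r


def fit_estimator(est: "PixelTransformer", X, y, cfg: TrainConfig,
                  X_val=None, y_val=None) -> TrainRecord:
    """Run the training loop and attach the fitted state to ``est``.

    Teacher forcing over full images: the input sequence is (seed, x_1 ..
    x_{r-1}) — the final pixel is never consumed — and the targets are
    (x_1 .. x_r).  Early stopping monitors validation NLL with dropout
    disabled and the best checkpoint is restored at the end.
    """
    t0 = time.perf_counter()
    X = np.asarray(X)
    y = np.asarray(y)
    if X.ndim != 3:
        raise ValueError("X must be (m, H, W) integer images")
    core = est._build_core()
    if X.shape[1] * X.shape[2] != core.config.n_pixels:
        raise ValueError("image size does not match the configured frame")
    idx = _label_indices(y, core.config.numerosities)

    rng = np.random.default_rng(cfg.seed)
    if X_val is None:
        m_val = max(1, int(round(len(X) * est.validation_fraction)))
        perm = rng.permutation(len(X))
        val_sel, tr_sel = perm[:m_val], perm[m_val:]
        X_val, y_val = X[val_sel], y[val_sel]
        X, idx = X[tr_sel], idx[tr_sel]
    else:
        X_val = np.asarray(X_val)
        y_val = np.asarray(y_val)

    m = len(X)
    r = core.config.n_pixels
    seq = X.reshape(m, r).astype(np.int64)
    opt = Adam(core.params(), lr=cfg.learning_rate)
    best_state = core.state_copy()
    best_val = evaluate_nll(core, X_val, y_val, batch_size=cfg.batch_size)
    best_epoch = 0
    rows: List[dict] = []
    stale = 0
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(m)
        run_sum, run_pos = 0.0, 0
        for lo in range(0, m, cfg.batch_size):
            sel = order[lo:lo + cfg.batch_size]
            batch = seq[sel]
            logits = core.forward(batch[:, :-1], core.Ws.value[idx[sel]],
                                  sos_index=idx[sel], train=True, rng=rng)
            run_sum += nll_loss(logits, batch, reduction="sum")
            run_pos += batch.size
            dlogits = cross_entropy_grad(logits, batch, reduction="mean")
            core.zero_grad()
            core.backward(dlogits)
            opt.step()
        train_pp = run_sum / run_pos
        val_pp = evaluate_nll(core, X_val, y_val, batch_size=cfg.batch_size)
        rows.append({"epoch": epoch,
                     "train_nll_per_pixel": train_pp,
                     "train_nll_per_image": train_pp * r,
                     "val_nll_per_pixel": val_pp,
                     "val_nll_per_image": val_pp * r})
        if val_pp < best_val - 1e-9:
            best_val, best_epoch, stale = val_pp, epoch, 0
            best_state = core.state_copy()
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    core.load_state(best_state)
    record = TrainRecord(history=pd.DataFrame(rows), best_epoch=best_epoch,
                         best_val_nll=best_val,
                         wall_time_s=time.perf_counter() - t0, config=cfg)
    est.core_ = core
    est.history_ = record.history
    est.train_record_ = record
    return record


def train(est: "PixelTransformer", bundle: "DatasetBundle",
          cfg: Optional[TrainConfig] = None) -> TrainRecord:
    """Fit an estimator on a dataset bundle's train split, validating on its
    validation split.  Without an explicit config the estimator's own
    optimisation parameters are used."""
    if cfg is None:
        cfg = TrainConfig(learning_rate=est.learning_rate,
                          batch_size=est.batch_size, epochs=est.epochs,
                          patience=est.patience, seed=est.seed)
    X, y = bundle.arrays("train")
    X_val, y_val = bundle.arrays("validation")
    return fit_estimator(est, X, y, cfg, X_val=X_val, y_val=y_val)


def loss_vs_train_size(est_factory, bundle: "DatasetBundle",
                       sizes: Sequence[int],
                       cfg: Optional[TrainConfig] = None) -> pd.DataFrame:
    """Best validation NLL as a function of training-set size.

    ``est_factory()`` must return a fresh unfitted estimator.  Subsets are
    nested — smaller training sets are prefixes of larger ones under one
    fixed shuffle — isolating the size effect.  The trend (more data, lower
    NLL) is reported, not asserted.
    """
    if list(sizes) != sorted(sizes):
        raise ValueError("sizes must be ascending")
    cfg = cfg or TrainConfig()
    X, y = bundle.arrays("train")
    X_val, y_val = bundle.arrays("validation")
    perm = np.random.default_rng(cfg.seed).permutation(len(X))
    rows = []
    for size in sizes:
        if size > len(X):
            raise ValueError(f"requested size {size} exceeds split "
                             f"({len(X)} images)")
        sel = perm[:size]
        record = fit_estimator(est_factory(), X[sel], y[sel], cfg,
                               X_val=X_val, y_val=y_val)
        rows.append({"train_size": size,
                     "best_val_nll_per_pixel": record.best_val_nll,
                     "best_epoch": record.best_epoch})
    return pd.DataFrame(rows)
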