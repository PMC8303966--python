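"""Centered PCA with a fixed sign convention, shared by the seed-probe
construction and the embedding analysis.

The convention: each principal component is flipped, if necessary, so that
its largest-magnitude loading is positive.  This removes the sign ambiguity
of the singular vectors and makes reduced-seed reports reproducible across
runs and BLAS builds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PCABasis:
    mean: np.ndarray                      # (d,)
    components: np.ndarray                # (k, d) orthonormal rows
    scores: np.ndarray                    # (n, k) projections of the input
    explained_variance_ratio: np.ndarray  # (k,), sums to 1

    def reconstruct(self, row: int, k: int) -> np.ndarray:
        """Rebuild input row ``row`` from its top-``k`` scores plus the mean."""
        if not 1 <= k <= self.components.shape[0]:
            raise ValueError(f"k must be in [1, {self.components.shape[0]}]")
        return self.mean + self.scores[row, :k] @ self.components[:k]


def fit_pca(W: np.ndarray) -> PCABasis:
    """Plain centered PCA (no whitening) of the rows of ``W``."""
    W = np.asarray(W, dtype=np.float64)
    if W.ndim != 2 or W.shape[0] < 2:
        raise ValueError("PCA needs a 2-D matrix with at least two rows")
    mean = W.mean(axis=0)
    Wc = W - mean
    U, S, Vt = np.linalg.svd(Wc, full_matrices=False)
    # fix signs: largest-magnitude loading of each component is positive
    flip = np.sign(Vt[np.arange(len(S)), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    scores = Wc @ Vt.T
    var = S ** 2
    total = var.sum()
    evr = var / total if total > 0 else np.full_like(var, 1.0 / len(var))
    return PCABasis(mean=mean, components=Vt, scores=scores,
                    explained_variance_ratio=evr)
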