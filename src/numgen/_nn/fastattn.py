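"""Fused causal-softmax kernels for the attention layer.

The causal mask makes almost half of the score matrix irrelevant; these
kernels normalise each row over its allowed prefix only and zero the rest,
in place, in a single pass.  numba provides the fused loop when available;
a plain numpy implementation is the fallback and the reference in tests.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised indirectly
    import numba

    @numba.njit(cache=False, fastmath=True)
    def _softmax_causal_nb(S):          # S: (M, q, q), modified in place
        M, q, _ = S.shape
        for m in range(M):
            for i in range(q):
                row = S[m, i]
                hi = row[0]
                for j in range(1, i + 1):
                    if row[j] > hi:
                        hi = row[j]
                total = 0.0
                for j in range(i + 1):
                    row[j] = np.exp(row[j] - hi)
                    total += row[j]
                for j in range(i + 1):
                    row[j] /= total
                for j in range(i + 1, q):
                    row[j] = 0.0

    @numba.njit(cache=False, fastmath=True)
    def _softmax_causal_grad_nb(A, dA):  # writes dS into dA, in place
        M, q, _ = A.shape
        for m in range(M):
            for i in range(q):
                arow = A[m, i]
                grow = dA[m, i]
                dot = 0.0
                for j in range(i + 1):
                    dot += arow[j] * grow[j]
                for j in range(i + 1):
                    grow[j] = arow[j] * (grow[j] - dot)
                for j in range(i + 1, q):
                    grow[j] = 0.0

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False


def softmax_causal(S: np.ndarray) -> np.ndarray:
    """In-place causal softmax over the last axis of (M, q, q) scores."""
    if HAVE_NUMBA:
        _softmax_causal_nb(S)
        return S
    q = S.shape[-1]
    neg = np.triu(np.full((q, q), -np.inf, dtype=S.dtype), 1)
    S += neg
    S -= S.max(axis=-1, keepdims=True)
    np.exp(S, out=S)
    np.nan_to_num(S, copy=False)
    S /= S.sum(axis=-1, keepdims=True)
    return S


def softmax_causal_grad(A: np.ndarray, dA: np.ndarray) -> np.ndarray:
    """In-place gradient of the causal softmax: dS = A * (dA - rowdot)."""
    if HAVE_NUMBA:
        _softmax_causal_grad_nb(A, dA)
        return dA
    dot = np.sum(A * dA, axis=-1, keepdims=True)
    dA -= dot
    dA *= A
    q = A.shape[-1]
    dA *= np.tril(np.ones((q, q), dtype=A.dtype))
    return dA
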