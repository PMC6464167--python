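"""Brute-force grid oracle for the inner simplex problem.

Enumerates the probability simplex at a fixed step and evaluates the
V-weighted predictor loss directly — independent arithmetic, no reuse of
the package's solver path. Supports K <= 4 donors (the K = 4 grid at step
0.001 has ~1.7e8 points and is enumerated in vectorized slabs).
"""

from __future__ import annotations

import numpy as np


def _loss_batch(W: np.ndarray, v, b1, B0, scale) -> np.ndarray:
    """Loss (b1 - B0 w)' diag(v) (b1 - B0 w) on scaled predictors, for a
    K x B batch of weight vectors."""
    resid = (b1[:, None] - B0 @ W) / scale[:, None]
    return v @ (resid * resid)


def grid_min_loss(v, b1, B0, scale, step: float = 0.001) -> float:
    """Minimum loss over the simplex grid with the given step."""
    v = np.asarray(v, float)
    b1 = np.asarray(b1, float)
    B0 = np.asarray(B0, float)
    scale = np.asarray(scale, float)
    v = v / v.sum()
    N, K = B0.shape
    m = round(1.0 / step)
    best = np.inf
    if K == 1:
        W = np.ones((1, 1))
        return float(_loss_batch(W, v, b1, B0, scale)[0])
    if K == 2:
        i = np.arange(m + 1)
        W = np.vstack([i, m - i]) / m
        return float(_loss_batch(W, v, b1, B0, scale).min())
    if K == 3:
        for i in range(m + 1):
            j = np.arange(m + 1 - i)
            W = np.vstack([np.full_like(j, i), j, m - i - j]) / m
            best = min(best, float(_loss_batch(W, v, b1, B0, scale).min()))
        return best
    if K == 4:
        for i in range(m + 1):
            m2 = m - i
            counts = m2 + 1 - np.arange(m2 + 1)
            jj = np.repeat(np.arange(m2 + 1), counts)
            offsets = np.repeat(np.cumsum(counts) - counts, counts)
            kk = np.arange(counts.sum()) - offsets
            W = np.vstack([np.full_like(jj, i), jj, kk, m - i - jj - kk]) / m
            best = min(best, float(_loss_batch(W, v, b1, B0, scale).min()))
        return best
    raise ValueError("grid oracle supports K <= 4")
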