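"""SMOTE: synthetic minority oversampling by convex interpolation between
minority-class nearest neighbours. Applied to training folds only; the
caller is responsible for never touching test data with it."""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["smote_oversample"]


def smote_oversample(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Balance a binary dataset by synthesizing minority samples.

    New points are x + u·(x_nn − x) with u ~ U(0,1) and x_nn one of the k
    nearest minority neighbours of x. If the minority class has fewer than
    k+1 samples, k is reduced (logged); identical minority points reproduce
    themselves. Returns (X, y) with equal class counts; already balanced
    input is returned unchanged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("SMOTE requires both classes present")
    if classes.size > 2:
        raise ValueError("binary labels expected")
    if counts[0] == counts[1]:
        return X, y
    minority = classes[np.argmin(counts)]
    n_needed = int(abs(counts[0] - counts[1]))
    Xm = X[y == minority]
    if len(Xm) < 2:
        raise ValueError("minority class needs at least 2 samples for interpolation")
    k = min(k_neighbors, len(Xm) - 1)
    if k < k_neighbors:
        logger.info("SMOTE k reduced from %d to %d (minority size %d)", k_neighbors, k, len(Xm))

    rng = np.random.default_rng(seed)
    d2 = ((Xm[:, None, :] - Xm[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    nn = np.argsort(d2, axis=1)[:, :k]

    base = rng.integers(0, len(Xm), size=n_needed)
    pick = rng.integers(0, k, size=n_needed)
    gaps = rng.uniform(size=n_needed)[:, None]
    neigh = Xm[nn[base, pick]]
    synthetic = Xm[base] + gaps * (neigh - Xm[base])

    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
    return X_out, y_out
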