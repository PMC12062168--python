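"""Feature-selection methods: ANOVA, Kruskal, MRMR, Relief, RFE.

Each method returns the top-k feature names with scores, ranked best first,
deterministically for a fixed seed. ANOVA and Kruskal are univariate
filters; MRMR greedily balances mutual-information relevance against mean
mutual-information redundancy with the already-selected set; Relief is
a binary ReliefF margin weighting with k nearest hits/misses; RFE recursively
eliminates features by logistic-regression coefficient magnitude.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.feature_selection import RFE, f_classif
from sklearn.linear_model import LogisticRegression

__all__ = ["FS_METHODS", "select_features"]

FS_METHODS = ("ANOVA", "Kruskal", "MRMR", "Relief", "RFE")


def _anova_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Features")
        f, _ = f_classif(X, y)
    return np.nan_to_num(f)


def _kruskal_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    groups = [X[y == c] for c in np.unique(y)]
    scores = np.zeros(X.shape[1])
    # constant columns make the tie correction 0/0; score them 0
    with np.errstate(invalid="ignore", divide="ignore"):
        for j in range(X.shape[1]):
            try:
                h, _ = stats.kruskal(*[g[:, j] for g in groups])
            except ValueError:  # all values identical
                h = 0.0
            scores[j] = h if np.isfinite(h) else 0.0
    return scores


def _quantile_bin(x: np.ndarray, n_bins: int = 3) -> np.ndarray:
    """Discretize a column into (up to) n_bins quantile bins."""
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.searchsorted(edges, x, side="right")


def _mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """MI (bits) of two discrete vectors via the contingency table."""
    na, nb = a.max() + 1, b.max() + 1
    joint = np.zeros((na, nb))
    np.add.at(joint, (a, b), 1.0)
    joint /= joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] / (pa @ pb)[nz])))


def _mrmr_rank(X: np.ndarray, y: np.ndarray, k: int) -> tuple[list[int], list[float]]:
    """Greedy MID scheme: score = MI-relevance − mean MI-redundancy.

    Mutual information puts relevance (bounded by label entropy) and
    redundancy (up to feature entropy) on one scale, so a duplicate of an
    already-selected feature is penalized past any relevance it carries.
    """
    n = X.shape[1]
    binned = [_quantile_bin(X[:, j]) for j in range(n)]
    yb = y.astype(int)
    rel = np.array([_mutual_information(binned[j], yb) for j in range(n)])
    selected: list[int] = []
    scores: list[float] = []
    first = int(np.argmax(rel))
    selected.append(first)
    scores.append(float(rel[first]))
    while len(selected) < min(k, n):
        remaining = [j for j in range(n) if j not in selected]
        mid = np.array([
            rel[j] - np.mean([_mutual_information(binned[j], binned[s]) for s in selected])
            for j in remaining
        ])
        best_pos = int(np.argmax(mid))
        selected.append(remaining[best_pos])
        scores.append(float(mid[best_pos]))
    return selected, scores


def _relief_scores(X: np.ndarray, y: np.ndarray, k_neighbors: int = 5) -> np.ndarray:
    """Binary ReliefF with k nearest hits and misses over all samples."""
    n, p = X.shape
    rng_range = X.max(axis=0) - X.min(axis=0)
    rng_range[rng_range == 0] = 1.0
    Xn = X / rng_range
    d2 = ((Xn[:, None, :] - Xn[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    w = np.zeros(p)
    for i in range(n):
        same = np.flatnonzero(y == y[i])
        same = same[same != i]
        diff = np.flatnonzero(y != y[i])
        if same.size == 0 or diff.size == 0:
            continue
        hits = same[np.argsort(d2[i, same])][:k_neighbors]
        misses = diff[np.argsort(d2[i, diff])][:k_neighbors]
        w -= np.abs(Xn[i] - Xn[hits]).mean(axis=0)
        w += np.abs(Xn[i] - Xn[misses]).mean(axis=0)
    return w / n


def select_features(
    method: str,
    X: pd.DataFrame,
    y: np.ndarray,
    k: int,
    seed: int = 0,
) -> tuple[list[str], np.ndarray]:
    """Rank features and return the top-k names with their scores."""
    if method not in FS_METHODS:
        raise ValueError(f"unknown FS method {method!r}; choose from {FS_METHODS}")
    y = np.asarray(y)
    if np.unique(y).size != 2:
        raise ValueError("select_features requires binary labels with both classes")
    n_feat = X.shape[1]
    if k > n_feat:
        warnings.warn(f"k={k} exceeds {n_feat} available features; capped", stacklevel=2)
        k = n_feat
    Xv = np.nan_to_num(X.to_numpy(dtype=float))
    cols = np.asarray(X.columns)

    if method == "MRMR":
        idx, sc = _mrmr_rank(Xv, y, k)
        return [str(c) for c in cols[idx]], np.asarray(sc)
    if method == "RFE":
        est = LogisticRegression(max_iter=1000, random_state=seed)
        rfe = RFE(est, n_features_to_select=k, step=0.2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rfe.fit(Xv, y)
        chosen = np.flatnonzero(rfe.support_)
        # order the survivors by final coefficient magnitude, largest first
        coefs = np.abs(rfe.estimator_.coef_).ravel()
        order = chosen[np.argsort(-coefs)]
        return [str(c) for c in cols[order]], coefs[np.argsort(-coefs)]

    if method == "ANOVA":
        scores = _anova_scores(Xv, y)
    elif method == "Kruskal":
        scores = _kruskal_scores(Xv, y)
    else:  # Relief
        scores = _relief_scores(Xv, y)
    # stable, name-tie-broken descending rank
    order = sorted(range(n_feat), key=lambda j: (-scores[j], str(cols[j])))[:k]
    return [str(c) for c in cols[order]], scores[order]
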