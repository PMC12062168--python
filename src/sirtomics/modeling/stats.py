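"""ROC/AUC statistics and univariate group screening.

Contains the bootstrap ROC confidence interval, the DeLong test for paired
AUCs (fast midrank algorithm), and Mann-Whitney / Fisher's-exact univariate
screening with Benjamini-Hochberg false-discovery-rate adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["auc_score", "bootstrap_roc", "delong_test", "univariate_group_tests"]


def auc_score(labels: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based AUC: the Mann-Whitney U statistic divided by n1*n0."""
    labels = np.asarray(labels).astype(bool)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels]
    neg = scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes required to compute AUC")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


@dataclass
class BootstrapAUC:
    auc: float
    ci_low: float
    ci_high: float
    n_bootstrap: int
    n_degenerate: int


def bootstrap_roc(
    scores: np.ndarray,
    labels: np.ndarray,
    n: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> BootstrapAUC:
    """Percentile bootstrap CI of the AUC, resampling cases with replacement.

    Resamples containing a single class carry no AUC; they are skipped and
    counted in ``n_degenerate``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    point = auc_score(labels, scores)
    rng = np.random.default_rng(seed)
    aucs = []
    degenerate = 0
    m = len(scores)
    for _ in range(n):
        idx = rng.integers(0, m, size=m)
        lb = labels[idx]
        if lb.all() or not lb.any():
            degenerate += 1
            continue
        aucs.append(auc_score(lb, scores[idx]))
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.percentile(aucs, [100 * alpha, 100 * (1 - alpha)])
    return BootstrapAUC(point, float(lo), float(hi), n, degenerate)


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_cov(scores_stack: np.ndarray, labels: np.ndarray):
    """AUCs and their DeLong covariance for k paired score vectors.

    Fast structural-components algorithm (Sun & Xu 2014 formulation).
    """
    order = np.argsort(~labels)  # positives first
    labels = labels[order]
    scores_stack = scores_stack[:, order]
    m = int(labels.sum())
    n = len(labels) - m
    k = scores_stack.shape[0]
    tx = np.empty((k, m))
    ty = np.empty((k, n))
    aucs = np.empty(k)
    v01 = np.empty((k, m))
    v10 = np.empty((k, n))
    for r in range(k):
        pos, neg = scores_stack[r, :m], scores_stack[r, m:]
        tz = _midrank(scores_stack[r])
        tx[r] = _midrank(pos)
        ty[r] = _midrank(neg)
        aucs[r] = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        v01[r] = (tz[:m] - tx[r]) / n
        v10[r] = 1.0 - (tz[m:] - ty[r]) / m
    sx = np.cov(v01)
    sy = np.cov(v10)
    cov = np.atleast_2d(sx) / m + np.atleast_2d(sy) / n
    return aucs, cov


def delong_test(scores_a, scores_b, labels) -> dict[str, float]:
    """Two-sided DeLong comparison of two correlated AUCs on the same cases.

    Returns ``auc_a``, ``auc_b`` and ``p_value``; a degenerate variance
    (e.g. both classifiers separate perfectly on identical cases) yields
    p = NaN, reported rather than fabricated.
    """
    labels = np.asarray(labels).astype(bool)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.shape[0] != labels.shape[0]:
        raise ValueError("paired scores and labels must have identical length")
    if labels.all() or not labels.any():
        raise ValueError("both classes required")
    aucs, cov = _delong_cov(np.vstack([a, b]), labels)
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var <= 0:
        p = 1.0 if aucs[0] == aucs[1] else float("nan")
    else:
        z = (aucs[0] - aucs[1]) / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
    return {"auc_a": float(aucs[0]), "auc_b": float(aucs[1]), "p_value": p}


def univariate_group_tests(
    X: pd.DataFrame,
    labels,
    categorical: list[str] | None = None,
    q: float = 0.05,
) -> pd.DataFrame:
    """Per-feature two-group screening with BH adjustment.

    Continuous columns are compared with the Mann-Whitney U test, columns
    named in ``categorical`` with Fisher's exact test on the 2x2 table.
    Returns raw p, BH-adjusted p, and significance flags before/after
    adjustment at level ``q``.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError("binary labels required")
    g0, g1 = labels == groups[0], labels == groups[1]
    categorical = set(categorical or [])
    records = []
    for col in X.columns:
        x = X[col].to_numpy()
        if col in categorical:
            tab = pd.crosstab(labels, x)
            if tab.shape == (2, 2):
                _, p = stats.fisher_exact(tab.to_numpy())
            else:
                p = 1.0
            test = "fisher"
        else:
            a, b = x[g0], x[g1]
            if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
                p = 1.0
            else:
                _, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            test = "mwu"
        records.append({"feature": col, "test": test, "p": float(p)})
    df = pd.DataFrame(records).set_index("feature")
    reject, p_adj, _, _ = multipletests(df["p"], alpha=q, method="fdr_bh")
    df["p_bh"] = p_adj
    df["significant_raw"] = df["p"] < q
    df["significant_bh"] = reject
    return df
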