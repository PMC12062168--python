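"""Fold-local preprocessing: Z-score normalization and redundancy pruning.

Both are *fit on the training fold only*: test data is transformed with the
training mean/sd, and the Spearman pruning decision (which column of a
correlated pair survives) is made from training data alone.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.feature_selection import f_classif

logger = logging.getLogger(__name__)

__all__ = ["zscore_fit_apply", "remove_redundant"]


def zscore_fit_apply(
    train_X: pd.DataFrame, test_X: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Z-score with training statistics (sample sd, ddof=1).

    Columns with zero training variance carry no information and are dropped
    from both sets (logged). Missing values are imputed with the training
    median before normalization.
    """
    if len(train_X) < 2:
        raise ValueError("need at least 2 training rows to normalize")
    train_X = train_X.replace([np.inf, -np.inf], np.nan)
    if test_X is not None:
        test_X = test_X.replace([np.inf, -np.inf], np.nan)
    med = train_X.median()
    train_X = train_X.fillna(med)
    mean = train_X.mean()
    sd = train_X.std(ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = list(train_X.columns[~keep])
        logger.info("dropping %d zero-variance columns: %s...", len(dropped), dropped[:5])
    cols = train_X.columns[keep]
    tr = (train_X[cols] - mean[cols]) / sd[cols]
    te = None
    if test_X is not None:
        te = ((test_X[cols].fillna(med[cols])) - mean[cols]) / sd[cols]
    return tr, te


def remove_redundant(
    X: pd.DataFrame,
    rho_threshold: float = 0.90,
    y: np.ndarray | None = None,
) -> pd.DataFrame:
    """Drop columns until no pair has |Spearman rho| >= threshold.

    Keep-rule: within a correlated pair, keep the column with the better
    univariate ANOVA F-score against ``y`` (when given), ties and the
    unlabeled case broken lexicographically by name. Deterministic.
    """
    if X.shape[1] < 2:
        return X
    rho = X.corr(method="spearman").abs().to_numpy()
    np.fill_diagonal(rho, 0.0)
    cols = list(X.columns)
    if y is not None:
        import warnings

        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="Features")
            scores, _ = f_classif(np.nan_to_num(X.to_numpy(dtype=float)), y)
        scores = np.nan_to_num(scores)
    else:
        scores = np.zeros(len(cols))
    # process best-scored first so they claim their correlation neighbourhood
    order = sorted(range(len(cols)), key=lambda i: (-scores[i], cols[i]))
    kept: list[int] = []
    for i in order:
        if all(rho[i, j] < rho_threshold for j in kept):
            kept.append(i)
    kept_names = [c for c in cols if c in {cols[i] for i in kept}]  # original order
    return X[kept_names]
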