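"""The eight classifiers and their hyperparameter grids.

Seven come from scikit-learn / xgboost. GLMB — boosting of a generalized
linear model — is realized as component-wise gradient boosting of univariate
linear base learners under the logistic loss: at each step the single
feature whose least-squares fit best explains the current residual updates
the additive log-odds. This yields a sparse, interpretable linear ensemble
in the spirit of mboost's glmboost.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted
from xgboost import XGBClassifier

__all__ = ["CLASSIFIERS", "DEFAULT_GRIDS", "make_classifier", "GLMBClassifier"]

CLASSIFIERS = ("DT", "GLMB", "LR", "MLP", "NB", "RF", "SVM", "XGB")


class GLMBClassifier(BaseEstimator, ClassifierMixin):
    """Component-wise boosted logistic regression.

    Parameters
    ----------
    n_estimators : int
        Boosting steps; each adds one univariate linear update.
    learning_rate : float
        Shrinkage applied to every update.
    """

    def __init__(self, n_estimators: int = 100, learning_rate: float = 0.1):
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("GLMB is a binary classifier")
        t = (y == self.classes_[1]).astype(float)
        n, p = X.shape
        self.intercept_ = float(np.log((t.mean() + 1e-9) / (1 - t.mean() + 1e-9)))
        self.coef_ = np.zeros(p)
        F = np.full(n, self.intercept_)
        xc = X - X.mean(axis=0)
        ss = (xc**2).sum(axis=0)
        ss[ss == 0] = np.inf
        for _ in range(self.n_estimators):
            prob = 1.0 / (1.0 + np.exp(-F))
            r = t - prob  # negative gradient of logistic loss
            slopes = xc.T @ r / ss
            sse_gain = slopes**2 * np.where(np.isinf(ss), 0.0, ss)
            j = int(np.argmax(sse_gain))
            if sse_gain[j] <= 0:
                break
            update = slopes[j] * xc[:, j] + r.mean()
            F += self.learning_rate * update
            self.coef_[j] += self.learning_rate * slopes[j]
            self.intercept_ += self.learning_rate * (r.mean() - slopes[j] * X[:, j].mean())
        self._fitted = True
        return self

    def decision_function(self, X):
        check_is_fitted(self, "_fitted")
        X = np.asarray(X, dtype=float)
        return X @ self.coef_ + self.intercept_

    def predict_proba(self, X):
        p1 = 1.0 / (1.0 + np.exp(-self.decision_function(X)))
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]


DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "DT": {"max_depth": [2, 3, 5]},
    "GLMB": {"n_estimators": [50, 100], "learning_rate": [0.1]},
    "LR": {"C": [0.1, 1.0, 10.0]},
    "MLP": {"hidden_layer_sizes": [(8,), (16,)], "alpha": [1e-3, 1e-2]},
    "NB": {},
    "RF": {"max_depth": [2, 4]},
    "SVM": {"C": [0.1, 1.0, 10.0], "kernel": ["linear", "rbf"]},
    "XGB": {"max_depth": [2, 3], "learning_rate": [0.1, 0.3]},
}


def make_classifier(name: str, params: dict | None = None, seed: int = 0):
    """Instantiate a classifier by short name with given hyperparameters."""
    params = dict(params or {})
    if name == "DT":
        return DecisionTreeClassifier(random_state=seed, **params)
    if name == "GLMB":
        return GLMBClassifier(**params)
    if name == "LR":
        return LogisticRegression(max_iter=2000, random_state=seed, **params)
    if name == "MLP":
        return MLPClassifier(max_iter=800, random_state=seed, **params)
    if name == "NB":
        return GaussianNB(**params)
    if name == "RF":
        return RandomForestClassifier(n_estimators=100, random_state=seed, **params)
    if name == "SVM":
        return SVC(probability=True, random_state=seed, **params)
    if name == "XGB":
        return XGBClassifier(
            n_estimators=50,
            eval_metric="logloss",
            random_state=seed,
            verbosity=0,
            **params,
        )
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIERS}")
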