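"""Nested cross-validated model evaluation and the 1440-model experiment.

For each (strategy, feature selector, classifier) triple the harness runs a
threefold nested CV: the outer loop gives unbiased test predictions, the
inner loop grid-searches hyperparameters (including the number of selected
features). Everything that learns from data — Z-scoring, Spearman redundancy
pruning, feature selection, SMOTE, hyperparameter choice — is fit inside
training folds only.

Pipeline per outer fold:
    z-score (train stats) -> Spearman prune (train) -> [inner loop: FS ->
    SMOTE -> fit -> validate] -> refit with best settings on the outer
    training fold (FS -> SMOTE -> fit) -> predict the outer test fold.

Metrics (AUC, ACC, SEN, SPE; positive class = responder) are reported both
pooled over the outer test predictions and averaged over folds.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .classifiers import CLASSIFIERS, DEFAULT_GRIDS, make_classifier
from .preprocessing import remove_redundant, zscore_fit_apply
from .sampling import smote_oversample
from .selection import FS_METHODS, select_features
from .stats import BootstrapAUC, auc_score, bootstrap_roc
from .strategies import StrategySpec, build_strategies, resolve_strategy

logger = logging.getLogger(__name__)

__all__ = ["ModelConfig", "ModelResult", "nested_cv_evaluate", "run_experiment", "metric_matrix"]

POSITIVE_LABEL = "R"


@dataclass
class ModelConfig:
    """Harness configuration with the study's defaults."""

    fs_methods: tuple[str, ...] = FS_METHODS
    classifiers: tuple[str, ...] = CLASSIFIERS
    outer_folds: int = 3
    inner_folds: int = 3
    spearman_rho_threshold: float = 0.90
    smote_k: int = 5
    n_bootstrap: int = 1000
    k_grid: tuple[int, ...] = (5, 10, 15)
    grids: dict[str, dict[str, list]] = field(default_factory=lambda: DEFAULT_GRIDS)
    smote_before_fs: bool = False
    seed: int = 0


@dataclass
class ModelResult:
    strategy: str
    fs: str
    classifier: str
    auc: float
    acc: float
    sen: float
    spe: float
    confusion: dict[str, int]
    fold_metrics: list[dict[str, float]]
    bootstrap: BootstrapAUC | None
    selected_features: dict[str, float]
    best_params: list[dict]
    scores: np.ndarray
    y_true: np.ndarray
    seed: int

    def to_row(self) -> dict:
        return {
            "strategy": self.strategy,
            "fs": self.fs,
            "classifier": self.classifier,
            "auc": self.auc,
            "acc": self.acc,
            "sen": self.sen,
            "spe": self.spe,
            **self.confusion,
            "auc_ci_low": self.bootstrap.ci_low if self.bootstrap else np.nan,
            "auc_ci_high": self.bootstrap.ci_high if self.bootstrap else np.nan,
        }


def _binary(y) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "USO":
        return (y == POSITIVE_LABEL).astype(int)
    return y.astype(int)


def _metrics(y_true: np.ndarray, scores: np.ndarray) -> dict[str, float]:
    pred = (scores >= 0.5).astype(int)
    tp = int(np.sum((pred == 1) & (y_true == 1)))
    tn = int(np.sum((pred == 0) & (y_true == 0)))
    fp = int(np.sum((pred == 1) & (y_true == 0)))
    fn = int(np.sum((pred == 0) & (y_true == 1)))
    sen = tp / (tp + fn) if tp + fn else float("nan")
    spe = tn / (tn + fp) if tn + fp else float("nan")
    return {
        "auc": auc_score(y_true.astype(bool), scores),
        "acc": (tp + tn) / len(y_true),
        "sen": sen,
        "spe": spe,
        "TP": tp,
        "TN": tn,
        "FP": fp,
        "FN": fn,
    }


def _param_grid(grid: dict[str, list]):
    if not grid:
        yield {}
        return
    keys = sorted(grid)
    for combo in itertools.product(*(grid[k] for k in keys)):
        yield dict(zip(keys, combo))


def _fit_predict(clf_name, params, Xtr, ytr, Xte, cfg, seed, fs_method, k,
                 fs_cache: dict | None = None, cache_key=None):
    """FS -> SMOTE -> fit on (Xtr, ytr); return scores on Xte and the FS output.

    The FS result depends only on (training fold, k), not on the classifier
    hyperparameters, so it can be cached across grid-search combos.
    """
    if fs_cache is not None and cache_key in fs_cache:
        names, scores = fs_cache[cache_key]
        if cfg.smote_before_fs:
            Xs, ys = smote_oversample(Xtr.to_numpy(dtype=float), ytr, cfg.smote_k, seed)
            Xs = pd.DataFrame(Xs, columns=Xtr.columns)
            Xfit, yfit = Xs[names].to_numpy(dtype=float), ys
        else:
            Xfit, yfit = smote_oversample(
                Xtr[names].to_numpy(dtype=float), ytr, cfg.smote_k, seed
            )
    elif cfg.smote_before_fs:
        Xs, ys = smote_oversample(Xtr.to_numpy(dtype=float), ytr, cfg.smote_k, seed)
        Xs = pd.DataFrame(Xs, columns=Xtr.columns)
        names, scores = select_features(fs_method, Xs, ys, k, seed)
        Xfit, yfit = Xs[names].to_numpy(dtype=float), ys
    else:
        names, scores = select_features(fs_method, Xtr, ytr, k, seed)
        Xfit, yfit = smote_oversample(
            Xtr[names].to_numpy(dtype=float), ytr, cfg.smote_k, seed
        )
    if fs_cache is not None and cache_key not in fs_cache:
        fs_cache[cache_key] = (names, scores)
    clf = make_classifier(clf_name, params, seed=seed)
    clf.fit(Xfit, yfit)
    te_scores = clf.predict_proba(Xte[names].to_numpy(dtype=float))[:, 1]
    return te_scores, names, scores


def nested_cv_evaluate(
    X: pd.DataFrame,
    y,
    fs_method: str,
    classifier: str,
    cfg: ModelConfig | None = None,
    strategy_name: str = "",
    compute_bootstrap: bool = True,
) -> ModelResult:
    """Run one (FS, classifier) pair through the full nested CV."""
    cfg = cfg or ModelConfig()
    yb = _binary(y)
    counts = np.bincount(yb, minlength=2)
    if np.min(counts) < cfg.outer_folds:
        raise ValueError(
            f"cannot stratify {cfg.outer_folds} outer folds with class counts "
            f"{counts.tolist()}"
        )
    outer = StratifiedKFold(cfg.outer_folds, shuffle=True, random_state=cfg.seed)
    pooled_scores = np.zeros(len(yb))
    fold_metrics: list[dict[str, float]] = []
    selected: dict[str, float] = {}
    best_params_per_fold: list[dict] = []

    for fold, (tr_idx, te_idx) in enumerate(outer.split(X, yb)):
        Xtr_raw, Xte_raw = X.iloc[tr_idx], X.iloc[te_idx]
        ytr, yte = yb[tr_idx], yb[te_idx]
        Xtr, Xte = zscore_fit_apply(Xtr_raw, Xte_raw)
        Xtr = remove_redundant(Xtr, cfg.spearman_rho_threshold, y=ytr)
        Xte = Xte[Xtr.columns]
        fold_seed = cfg.seed + 17 * (fold + 1)

        # inner grid search over (k, hyperparameters)
        k_options = sorted({min(k, Xtr.shape[1]) for k in cfg.k_grid})
        combos = [
            (k, params)
            for k in k_options
            for params in _param_grid(cfg.grids.get(classifier, {}))
        ]
        best_combo, best_score = combos[0], -np.inf
        if len(combos) > 1:
            inner = StratifiedKFold(cfg.inner_folds, shuffle=True, random_state=fold_seed)
            n_inner = min(cfg.inner_folds, int(np.min(np.bincount(ytr, minlength=2))))
            if n_inner >= 2:
                inner = StratifiedKFold(n_inner, shuffle=True, random_state=fold_seed)
                splits = list(inner.split(Xtr, ytr))
                fs_cache: dict = {}
                for combo in combos:
                    k, params = combo
                    aucs = []
                    for i_split, (itr, iva) in enumerate(splits):
                        yi_tr, yi_va = ytr[itr], ytr[iva]
                        if yi_va.min() == yi_va.max() or np.min(np.bincount(yi_tr)) < 2:
                            continue
                        try:
                            sc, _, _ = _fit_predict(
                                classifier, params, Xtr.iloc[itr], yi_tr,
                                Xtr.iloc[iva], cfg, fold_seed, fs_method, k,
                                fs_cache=fs_cache, cache_key=(i_split, k),
                            )
                            aucs.append(auc_score(yi_va.astype(bool), sc))
                        except ValueError:
                            continue
                    score = float(np.mean(aucs)) if aucs else -np.inf
                    if score > best_score:
                        best_combo, best_score = combo, score

        k_best, params_best = best_combo
        best_params_per_fold.append({"k": k_best, **params_best})
        te_scores, names, fs_scores = _fit_predict(
            classifier, params_best, Xtr, ytr, Xte, cfg, fold_seed, fs_method, k_best
        )
        pooled_scores[te_idx] = te_scores
        fold_metrics.append(_metrics(yte, te_scores))
        for n, s in zip(names, np.asarray(fs_scores, dtype=float)):
            selected[n] = max(selected.get(n, -np.inf), float(s))

    pooled = _metrics(yb, pooled_scores)
    boot = (
        bootstrap_roc(pooled_scores, yb, n=cfg.n_bootstrap, seed=cfg.seed)
        if compute_bootstrap
        else None
    )
    return ModelResult(
        strategy=strategy_name,
        fs=fs_method,
        classifier=classifier,
        auc=pooled["auc"],
        acc=pooled["acc"],
        sen=pooled["sen"],
        spe=pooled["spe"],
        confusion={k: pooled[k] for k in ("TP", "TN", "FP", "FN")},
        fold_metrics=fold_metrics,
        bootstrap=boot,
        selected_features=selected,
        best_params=best_params_per_fold,
        scores=pooled_scores,
        y_true=yb,
        seed=cfg.seed,
    )


def run_experiment(
    tables: dict[str, pd.DataFrame],
    labels,
    cfg: ModelConfig | None = None,
    strategies: list[StrategySpec] | None = None,
    train: bool = True,
) -> tuple[pd.DataFrame, list[ModelResult]]:
    """Run (or enumerate) the full strategy x FS x classifier grid.

    With ``train=False`` the grid is enumerated without fitting — useful to
    verify the model count. Unsatisfiable strategies (missing tables) are
    skipped and counted in ``df.attrs["n_skipped"]``.
    """
    cfg = cfg or ModelConfig()
    specs = strategies if strategies is not None else build_strategies(tables)
    rows: list[dict] = []
    results: list[ModelResult] = []
    n_skipped = 0
    model_index = 0
    for spec in specs:
        if not spec.satisfiable:
            n_skipped += len(cfg.fs_methods) * len(cfg.classifiers)
            logger.warning("skipping %s (missing tables: %s)", spec.name, spec.missing)
            continue
        X = resolve_strategy(spec, tables) if train else None
        for fs in cfg.fs_methods:
            for clf in cfg.classifiers:
                model_index += 1
                if not train:
                    rows.append(
                        {"strategy": spec.name, "fs": fs, "classifier": clf,
                         "status": "enumerated"}
                    )
                    continue
                model_cfg = ModelConfig(**{**cfg.__dict__,
                                           "seed": (cfg.seed * 1000003 + model_index) % 2**31})
                res = nested_cv_evaluate(
                    X, labels, fs, clf, model_cfg, strategy_name=spec.name,
                    compute_bootstrap=False,
                )
                results.append(res)
                rows.append(res.to_row() | {"status": "trained"})
    df = pd.DataFrame(rows)
    df.attrs["n_skipped"] = n_skipped
    return df, results


def metric_matrix(results_df: pd.DataFrame, metric: str = "auc") -> pd.DataFrame:
    """Heatmap-ready strategy x (FS, classifier) matrix of one metric."""
    df = results_df.copy()
    df["fs_ml"] = df["fs"] + "+" + df["classifier"]
    return df.pivot(index="strategy", columns="fs_ml", values=metric)
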