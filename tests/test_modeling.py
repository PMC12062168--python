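"""ML harness: preprocessing, selection, SMOTE, CV, strategies, statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sirtomics.modeling import (
    CLASSIFIERS,
    FS_METHODS,
    GLMBClassifier,
    ModelConfig,
    auc_score,
    bootstrap_roc,
    build_strategies,
    delong_test,
    make_classifier,
    metric_matrix,
    nested_cv_evaluate,
    remove_redundant,
    resolve_strategy,
    run_experiment,
    select_features,
    smote_oversample,
    univariate_group_tests,
    zscore_fit_apply,
)


def _toy_xy(n=60, p=12, effect=3.0, seed=0, n_pos=None):
    rng = np.random.default_rng(seed)
    y = np.zeros(n, dtype=int)
    y[: (n_pos if n_pos is not None else n // 2)] = 1
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"f{i}" for i in range(p)])
    X["informative"] = y * effect + rng.normal(size=n)
    return X, y


class TestZScore:
    def test_hand_example_sample_sd(self):
        tr = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        te = pd.DataFrame({"a": [2.0]})
        ztr, zte = zscore_fit_apply(tr, te)
        assert ztr["a"].tolist() == pytest.approx([-1.0, 0.0, 1.0])  # ddof=1
        assert zte["a"].tolist() == pytest.approx([0.0])

    def test_idempotent_on_normalized(self):
        rng = np.random.default_rng(0)
        tr = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        z1, _ = zscore_fit_apply(tr)
        z2, _ = zscore_fit_apply(z1)
        pd.testing.assert_frame_equal(z1, z2, atol=1e-12, check_exact=False)

    def test_zero_variance_column_dropped(self):
        tr = pd.DataFrame({"a": [1.0, 2.0, 3.0], "const": [5.0, 5.0, 5.0]})
        ztr, _ = zscore_fit_apply(tr)
        assert list(ztr.columns) == ["a"]


class TestRedundancy:
    def test_duplicate_column_removed(self):
        X, y = _toy_xy(n=40)
        X["dup"] = X["informative"]
        red = remove_redundant(X, 0.90, y=y)
        assert ("informative" in red.columns) != ("dup" in red.columns) or \
            "dup" not in red.columns
        # no remaining pair above threshold
        rho = red.corr(method="spearman").abs().to_numpy()
        np.fill_diagonal(rho, 0)
        assert rho.max() < 0.90

    def test_monotone_transform_removed(self):
        X, y = _toy_xy(n=40)
        X["mono"] = np.exp(X["informative"])  # Spearman rho = 1
        red = remove_redundant(X, 0.90, y=y)
        assert not ({"informative", "mono"} <= set(red.columns))

    def test_independent_columns_kept(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(100, 2)), columns=["a", "b"])
        red = remove_redundant(X, 0.90)
        assert red.shape[1] == 2

    def test_keeps_better_scored_of_pair(self):
        X, y = _toy_xy(n=40)
        X["dup"] = X["informative"] + 1e-9  # rank-identical
        red = remove_redundant(X, 0.90, y=y)
        assert "informative" in red.columns  # higher F than noisy alias? equal
        assert red.shape[1] == X.shape[1] - 1


class TestSelection:
    @pytest.mark.parametrize("method", FS_METHODS)
    def test_informative_feature_ranked_first(self, method):
        X, y = _toy_xy(n=60, effect=4.0, seed=2)
        names, scores = select_features(method, X, y, k=3, seed=0)
        assert names[0] == "informative"

    def test_null_anova_pvalues_uniformish(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(80, 40))
        y = np.array([0, 1] * 40)
        from sklearn.feature_selection import f_classif

        _, p = f_classif(X, y)
        # under the null, ~5% of p-values below 0.05 (binomial slack)
        assert (p < 0.05).mean() < 0.20
        _, ks_p = stats.kstest(p, "uniform")
        assert ks_p > 0.01

    def test_mrmr_skips_duplicate_matches_bruteforce(self):
        """On 3 features (informative, its duplicate, independent noise),
        greedy MRMR must pick the informative one then the non-redundant
        one, matching an exhaustive search over 2-subsets under the
        (MI relevance - mean MI redundancy) objective computed naively."""
        rng = np.random.default_rng(4)
        y = np.array([0] * 30 + [1] * 30)
        a = y * 3.0 + rng.normal(size=60)
        X = pd.DataFrame({"a": a, "a_dup": a + rng.normal(size=60) * 0.01,
                          "b": rng.normal(size=60)})
        names, _ = select_features("MRMR", X, y, k=2)

        def naive_mi(u, v):
            # plain double loop over the contingency table, bits
            mi, n = 0.0, len(u)
            for uu in set(u):
                for vv in set(v):
                    pj = sum((u == uu) & (v == vv)) / n
                    if pj > 0:
                        pu, pv = sum(u == uu) / n, sum(v == vv) / n
                        mi += pj * np.log2(pj / (pu * pv))
            return mi

        def bins(x):
            return pd.qcut(x, 3, labels=False, duplicates="drop").to_numpy()

        cols = list(X.columns)
        binned = {c: bins(X[c]) for c in cols}
        rel = {c: naive_mi(binned[c], y) for c in cols}
        best_pair, best_val = None, -np.inf
        for pair in itertools.combinations(cols, 2):
            red = naive_mi(binned[pair[0]], binned[pair[1]])
            val = rel[pair[0]] + rel[pair[1]] - red
            if val > best_val:
                best_pair, best_val = pair, val
        assert set(names) == set(best_pair)
        assert names[0] in ("a", "a_dup")
        assert "b" in names

    def test_k_capped_with_warning(self):
        X, y = _toy_xy(n=30, p=4)
        with pytest.warns(UserWarning, match="capped"):
            names, _ = select_features("ANOVA", X, y, k=50)
        assert len(names) == X.shape[1]

    def test_deterministic(self):
        X, y = _toy_xy(n=40, seed=5)
        for method in FS_METHODS:
            a = select_features(method, X, y, 5, seed=9)[0]
            b = select_features(method, X, y, 5, seed=9)[0]
            assert a == b


class TestSMOTE:
    def test_balances_5_vs_12(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(17, 6))
        y = np.array([1] * 5 + [0] * 12)
        Xo, yo = smote_oversample(X, y, seed=1)
        assert np.bincount(yo).tolist() == [12, 12]
        assert Xo.shape == (24, 6)

    def test_balanced_input_unchanged(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 3))
        y = np.array([0, 1] * 5)
        Xo, yo = smote_oversample(X, y)
        assert np.array_equal(Xo, X) and np.array_equal(yo, y)

    def test_synthetic_points_are_convex_combinations(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(size=(4, 2)), rng.normal(5, 1, size=(12, 2))])
        y = np.array([1] * 4 + [0] * 12)
        Xo, yo = smote_oversample(X, y, seed=3)
        Xm = X[:4]
        lo, hi = Xm.min(axis=0), Xm.max(axis=0)
        synth = Xo[16:]
        assert np.all(synth >= lo - 1e-12) and np.all(synth <= hi + 1e-12)

    def test_identical_minority_points_reproduce_themselves(self):
        X = np.vstack([np.ones((2, 3)), np.zeros((5, 3))])
        y = np.array([1, 1, 0, 0, 0, 0, 0])
        Xo, yo = smote_oversample(X, y, seed=0)
        assert np.all(Xo[7:] == 1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            smote_oversample(np.ones((4, 2)), np.zeros(4))


class TestGLMB:
    def test_learns_linear_signal(self):
        X, y = _toy_xy(n=80, effect=3.0, seed=6)
        clf = GLMBClassifier(n_estimators=100).fit(X.to_numpy(), y)
        auc = auc_score(y.astype(bool), clf.predict_proba(X.to_numpy())[:, 1])
        assert auc > 0.9
        # component-wise: most mass on the informative coefficient
        assert np.argmax(np.abs(clf.coef_)) == X.columns.get_loc("informative")

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        clf = GLMBClassifier(n_estimators=7, learning_rate=0.3)
        c2 = clone(clf)
        assert c2.get_params() == clf.get_params()

    @pytest.mark.parametrize("name", CLASSIFIERS)
    def test_registry_instantiates_and_fits(self, name):
        X, y = _toy_xy(n=30, p=4, seed=7)
        clf = make_classifier(name, seed=0)
        clf.fit(X.to_numpy(), y)
        proba = clf.predict_proba(X.to_numpy())
        assert proba.shape == (30, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)


class TestStrategies:
    def test_exactly_36(self):
        specs = build_strategies()
        assert len(specs) == 36
        assert len({s.name for s in specs}) == 36
        cats = {s.category for s in specs}
        assert len(cats) == 6
        for c in cats:
            assert sum(1 for s in specs if s.category == c) == 6

    def test_clinical_mix_count(self):
        specs = build_strategies()
        assert sum(1 for s in specs if s.uses_clinical) == 18

    def test_missing_clinical_flags_unsatisfiable(self):
        tables = {k: pd.DataFrame({"x": [1.0, 2.0]}) for k in
                  ("CT", "SPECT_MAA", "SPECT_Y90", "MAA_Dose", "MAA_BED",
                   "Y90_Dose", "Y90_BED", "DVC")}
        tables["clinical"] = None
        specs = build_strategies(tables)
        assert len(specs) == 36
        unsat = [s for s in specs if not s.satisfiable]
        assert len(unsat) == 18
        assert all(s.uses_clinical for s in unsat)

    def test_resolution_prefixes_and_excludes(self):
        idx = ["c0", "c1", "c2", "c3"]
        ct = pd.DataFrame({"label": list("RNRN"), "f1": [1.0, 2, 3, 4]}, index=idx)
        clin = pd.DataFrame({"age_y": [60.0, 70, 65, 58], "sex": [0, 1, 0, 1]}, index=idx)
        tables = {"CT": ct, "clinical": clin}
        spec = [s for s in build_strategies()
                if s.name == "MAA-radiomics/CT+Clinical"][0]
        X = resolve_strategy(spec, tables)
        assert list(X.columns) == ["CT__f1", "clinical__age_y"]  # sex excluded

    def test_dvh_strategy_selects_kind_columns(self):
        idx = ["c0", "c1"]
        dvc = pd.DataFrame(
            {"label": ["R", "NR"],
             "tumor_Y90_Dose_D_mean": [1.0, 2.0],
             "tumor_Y90_BED_D_mean": [3.0, 4.0],
             "tumor_MAA_Dose_D_mean": [5.0, 6.0],
             "LSF": [0.05, 0.1], "injected_activity_GBq": [2.0, 3.0]},
            index=idx,
        )
        spec = [s for s in build_strategies() if s.name == "Y90-DVH/Dose"][0]
        X = resolve_strategy(spec, {"DVC": dvc})
        assert set(X.columns) == {
            "DVC_Y90_Dose__tumor_Y90_Dose_D_mean",
            "DVC_Y90_Dose__LSF",
            "DVC_Y90_Dose__injected_activity_GBq",
        }


class TestNestedCV:
    def test_deterministic_same_seed(self):
        X, y = _toy_xy(n=24, n_pos=8, seed=8)
        cfg = ModelConfig(seed=5, n_bootstrap=50)
        a = nested_cv_evaluate(X, y, "ANOVA", "RF", cfg)
        b = nested_cv_evaluate(X, y, "ANOVA", "RF", cfg)
        assert np.array_equal(a.scores, b.scores)
        assert a.to_row() == b.to_row()

    def test_infeasible_stratification_raises(self):
        X, y = _toy_xy(n=10, n_pos=2)
        with pytest.raises(ValueError, match="class counts"):
            nested_cv_evaluate(X, y, "ANOVA", "LR", ModelConfig(outer_folds=3))

    def test_confusion_matrix_sums_to_n(self):
        X, y = _toy_xy(n=24, n_pos=8, seed=9)
        r = nested_cv_evaluate(X, y, "Kruskal", "NB", ModelConfig(seed=2),
                               compute_bootstrap=False)
        assert sum(r.confusion.values()) == 24
        for m in (r.auc, r.acc):
            assert 0.0 <= m <= 1.0

    def test_train_only_data_reaches_fitting(self, monkeypatch):
        """Leakage guard: feature selection and SMOTE must only ever see
        training-fold rows (at most n - smallest-test-fold samples)."""
        import sirtomics.modeling.nested_cv as ncv

        X, y = _toy_xy(n=24, n_pos=8, seed=10)
        seen_fs, seen_smote = [], []
        orig_fs, orig_smote = ncv.select_features, ncv.smote_oversample

        def spy_fs(method, Xa, ya, k, seed=0):
            seen_fs.append(len(Xa))
            return orig_fs(method, Xa, ya, k, seed)

        def spy_smote(Xa, ya, k, seed):
            seen_smote.append(len(Xa))
            return orig_smote(Xa, ya, k, seed)

        monkeypatch.setattr(ncv, "select_features", spy_fs)
        monkeypatch.setattr(ncv, "smote_oversample", spy_smote)
        nested_cv_evaluate(X, y, "ANOVA", "NB", ModelConfig(seed=0),
                           compute_bootstrap=False)
        assert seen_fs and seen_smote
        assert max(seen_fs) <= 16  # outer-train size for 24 cases / 3 folds
        assert max(seen_smote) <= 16


class TestExperimentGrid:
    def _full_tables(self):
        idx = [f"c{i}" for i in range(17)]
        rng = np.random.default_rng(0)
        tables = {}
        for k in ("CT", "SPECT_MAA", "SPECT_Y90", "MAA_Dose", "MAA_BED",
                  "Y90_Dose", "Y90_BED"):
            tables[k] = pd.DataFrame(rng.normal(size=(17, 4)),
                                     columns=[f"{k}_f{j}" for j in range(4)], index=idx)
        tables["DVC"] = pd.DataFrame(
            {f"tumor_{c}_{kk}_D_mean": rng.normal(size=17)
             for c in ("MAA", "Y90") for kk in ("Dose", "BED")}
            | {"LSF": rng.uniform(size=17), "injected_activity_GBq": rng.uniform(1, 3, 17)},
            index=idx,
        )
        tables["clinical"] = pd.DataFrame({"age_y": rng.normal(65, 8, 17)}, index=idx)
        return tables

    def test_enumeration_1440(self):
        tables = self._full_tables()
        labels = ["R"] * 5 + ["NR"] * 12
        df, _ = run_experiment(tables, labels, ModelConfig(seed=0), train=False)
        assert len(df) == 1440
        assert df.attrs["n_skipped"] == 0

    def test_withheld_category_1200(self):
        tables = self._full_tables()
        tables["MAA_Dose"] = None
        tables["MAA_BED"] = None
        labels = ["R"] * 5 + ["NR"] * 12
        df, _ = run_experiment(tables, labels, ModelConfig(seed=0), train=False)
        assert len(df) == 1200
        assert df.attrs["n_skipped"] == 240

    def test_trained_subset_and_matrix_labels(self):
        tables = self._full_tables()
        labels = np.array(["R"] * 5 + ["NR"] * 12)
        cfg = ModelConfig(fs_methods=("ANOVA",), classifiers=("NB",), seed=1,
                          k_grid=(3,))
        specs = [s for s in build_strategies(tables) if s.category == "Y90-DVH"]
        df, results = run_experiment(tables, labels, cfg, strategies=specs)
        assert len(df) == 6
        assert len(results) == 6
        mat = metric_matrix(df, "auc")
        assert mat.shape == (6, 1)
        assert set(df["strategy"]) == {s.name for s in specs}


class TestROCStats:
    def test_bootstrap_perfect_separation(self):
        y = np.array([1] * 5 + [0] * 12)
        s = y.astype(float)
        b = bootstrap_roc(s, y, n=200, seed=0)
        assert b.auc == 1.0 and b.ci_low == 1.0 and b.ci_high == 1.0

    def test_bootstrap_null_covers_half(self):
        rng = np.random.default_rng(0)
        cover = 0
        for rep in range(20):
            y = np.array([1] * 50 + [0] * 50)
            s = rng.normal(size=100)
            b = bootstrap_roc(s, y, n=300, seed=rep)
            cover += b.ci_low <= 0.5 <= b.ci_high
        assert cover >= 18  # >= 90% coverage

    def test_bootstrap_deterministic(self):
        rng = np.random.default_rng(1)
        y = np.array([1] * 8 + [0] * 8)
        s = rng.normal(size=16)
        a = bootstrap_roc(s, y, n=100, seed=3)
        b = bootstrap_roc(s, y, n=100, seed=3)
        assert (a.auc, a.ci_low, a.ci_high) == (b.auc, b.ci_low, b.ci_high)

    def test_delong_identical_scores_p_one(self):
        y = np.array([1, 1, 0, 0, 1, 0])
        s = np.array([0.9, 0.7, 0.4, 0.2, 0.6, 0.5])
        r = delong_test(s, s, y)
        assert r["p_value"] == 1.0
        assert r["auc_a"] == r["auc_b"]

    def test_delong_auc_equals_mann_whitney_u(self):
        rng = np.random.default_rng(2)
        y = rng.uniform(size=40) > 0.5
        y[:2] = [True, False]
        s = rng.normal(size=40) + y * 0.8
        r = delong_test(s, rng.normal(size=40), y)
        u, _ = stats.mannwhitneyu(s[y], s[~y], alternative="two-sided")
        assert r["auc_a"] == pytest.approx(u / (y.sum() * (~y).sum()), abs=1e-12)

    def test_delong_matches_exact_swap_permutation_n10(self):
        """At n=10 the DeLong normal approximation should agree with the
        exact paired swap-permutation distribution of |dAUC| to ~0.15."""
        rng = np.random.default_rng(0)
        y = np.array([1] * 4 + [0] * 6, bool)
        a = rng.normal(size=10) + y * 1.0
        b = rng.normal(size=10) + y * 0.3
        r = delong_test(a, b, y)
        obs = abs(auc_score(y, a) - auc_score(y, b))
        count = 0
        for swaps in itertools.product([0, 1], repeat=10):
            sw = np.array(swaps, bool)
            aa, bb = np.where(sw, b, a), np.where(sw, a, b)
            if abs(auc_score(y, aa) - auc_score(y, bb)) >= obs - 1e-12:
                count += 1
        p_exact = count / 2**10
        assert r["p_value"] == pytest.approx(p_exact, abs=0.15)


class TestUnivariateScreening:
    def test_single_feature_bh_equals_raw(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"a": rng.normal(size=20)})
        y = np.array(["R"] * 10 + ["NR"] * 10)
        df = univariate_group_tests(X, y)
        assert df.loc["a", "p_bh"] == pytest.approx(df.loc["a", "p"])

    def test_huge_effect_survives_bh(self):
        rng = np.random.default_rng(1)
        y = np.array(["R"] * 15 + ["NR"] * 15)
        X = pd.DataFrame(rng.normal(size=(30, 50)), columns=[f"n{i}" for i in range(50)])
        X["effect"] = (y == "R") * 8.0 + rng.normal(size=30)
        df = univariate_group_tests(X, y)
        assert bool(df.loc["effect", "significant_bh"])

    def test_all_null_controls_fdr(self):
        """With 300 pure-noise features, BH yields any discovery in at most
        ~q of repetitions."""
        rng = np.random.default_rng(2)
        y = np.array(["R"] * 12 + ["NR"] * 12)
        reps_with_discovery = 0
        n_reps = 40
        for rep in range(n_reps):
            X = pd.DataFrame(rng.normal(size=(24, 300)))
            X.columns = [f"f{i}" for i in range(300)]
            df = univariate_group_tests(X, y)
            reps_with_discovery += int(df["significant_bh"].any())
        assert reps_with_discovery / n_reps <= 0.15

    def test_fisher_for_categorical(self):
        y = np.array(["R"] * 10 + ["NR"] * 10)
        X = pd.DataFrame({"cat": [1] * 9 + [0] * 11})
        df = univariate_group_tests(X, y, categorical=["cat"])
        assert df.loc["cat", "test"] == "fisher"
        assert 0 <= df.loc["cat", "p"] <= 1
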