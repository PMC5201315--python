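import numpy as np
import pandas as pd
import pytest

from fatiguelab import gasvm


def blobs(n=60, sep=6.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [rng.normal(0.0, 1.0, (n // 2, 2)), rng.normal(sep, 1.0, (n - n // 2, 2))]
    )
    y = np.r_[-np.ones(n // 2, dtype=int), np.ones(n - n // 2, dtype=int)]
    return X, y


def level_table(n_per_level=80, seed=0, sep=1.0) -> pd.DataFrame:
    """Three well-separated 2-D level clusters in (RT, alpha/beta) space."""
    rng = np.random.default_rng(seed)
    rows = []
    rt_means = {1: 1.21, 2: 1.30, 3: 1.40}
    ab_means = {1: 0.8, 2: 1.5, 3: 2.2}
    for lev in (1, 2, 3):
        rows.append(
            pd.DataFrame(
                {
                    "reaction_time_s": rng.normal(rt_means[lev], 0.02 / sep, n_per_level),
                    "alpha_over_beta": rng.normal(ab_means[lev], 0.08 / sep, n_per_level),
                    "level": lev,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


class TestBinarySVM:
    def test_separable_blobs_high_training_accuracy(self):
        X, y = blobs()
        model = gasvm.train_binary_svm(X, y, gasvm.SVMSpec(C=1.0, g=1.0))
        assert np.mean(model.predict(X) == y) >= 0.99

    def test_xor_fit_with_large_c(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        y = np.array([-1, 1, 1, -1])
        model = gasvm.train_binary_svm(X, y, gasvm.SVMSpec(C=1e6, g=2.0))
        np.testing.assert_array_equal(model.predict(X), y)

    def test_duplication_invariance(self):
        X, y = blobs(40)
        a = gasvm.train_binary_svm(X, y, gasvm.SVMSpec(C=2.0, g=0.5))
        b = gasvm.train_binary_svm(
            np.vstack([X, X]), np.r_[y, y], gasvm.SVMSpec(C=2.0, g=0.5)
        )
        grid = np.random.default_rng(0).normal(3.0, 3.0, (50, 2))
        np.testing.assert_array_equal(a.predict(grid), b.predict(grid))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            gasvm.train_binary_svm(np.zeros((5, 2)), np.ones(5, dtype=int), gasvm.SVMSpec(1, 1))

    def test_non_finite_rejected(self):
        X, y = blobs(10)
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            gasvm.train_binary_svm(X, y, gasvm.SVMSpec(1, 1))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            gasvm.SVMSpec(C=0.0, g=1.0)
        with pytest.raises(ValueError):
            gasvm.SVMSpec(C=1.0, g=-1.0)

    def test_dual_feasibility(self):
        X, y = blobs(50, sep=2.5, seed=3)
        spec = gasvm.SVMSpec(C=5.0, g=0.7)
        model = gasvm.train_binary_svm(X, y, spec)
        alphas = model.alphas
        assert np.all(alphas >= -1e-6) and np.all(alphas <= spec.C + 1e-6)
        assert abs(model.dual_coef_.sum()) < 1e-6  # sum alpha_i y_i = 0

    def test_serialization_roundtrip(self, tmp_path):
        table = level_table(30)
        model, _ = gasvm.train_hierarchical(
            table, specs=(gasvm.SVMSpec(10, 1), gasvm.SVMSpec(10, 1))
        )
        path = tmp_path / "model.json"
        model.to_json(path)
        restored = gasvm.HierarchicalModel.from_json(path)
        X = table[list(model.feature_cols)].to_numpy()
        np.testing.assert_array_equal(
            gasvm.predict(model, X), gasvm.predict(restored, X)
        )


class TestKFoldCV:
    def test_perfectly_separable_scores_one(self):
        X, y = blobs(80, sep=8.0)
        assert gasvm.kfold_cv_accuracy(X, y, gasvm.SVMSpec(1, 1), k=5) == 1.0

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(0)
        accs = []
        for rep in range(20):
            X = rng.standard_normal((60, 2))
            y = np.r_[-np.ones(30, dtype=int), np.ones(30, dtype=int)]
            rng.shuffle(y)
            accs.append(gasvm.kfold_cv_accuracy(X, y, gasvm.SVMSpec(1, 1), k=5, seed=rep))
        assert abs(np.mean(accs) - 0.5) < 0.1

    def test_deterministic_given_seed(self):
        X, y = blobs(60, sep=2.0, seed=5)
        a = gasvm.kfold_cv_accuracy(X, y, gasvm.SVMSpec(2, 1), k=10, seed=3)
        b = gasvm.kfold_cv_accuracy(X, y, gasvm.SVMSpec(2, 1), k=10, seed=3)
        assert a == b

    def test_small_class_falls_back_unstratified(self):
        X, y = blobs(40)
        y = y.copy()
        y[:37] = -1  # positive class smaller than K
        with pytest.warns(UserWarning, match="unstratified"):
            acc = gasvm.kfold_cv_accuracy(X, y, gasvm.SVMSpec(1, 1), k=10)
        assert 0.0 <= acc <= 1.0

    def test_k_too_small_rejected(self):
        X, y = blobs(20)
        with pytest.raises(ValueError):
            gasvm.kfold_cv_accuracy(X, y, gasvm.SVMSpec(1, 1), k=1)


class TestGA:
    def test_trace_monotone_nondecreasing(self):
        X, y = blobs(40, sep=1.5, seed=2)
        cfg = gasvm.GAConfig(population=6, generations=8, cv_folds=4, rng_seed=0)
        res = gasvm.ga_optimize(X, y, cfg)
        assert all(b >= a for a, b in zip(res.trace, res.trace[1:]))
        assert res.best_fitness == res.trace[-1]

    def test_matches_coarse_grid_on_separable_data(self):
        X, y = blobs(60, sep=5.0, seed=1)
        cfg = gasvm.GAConfig(population=8, generations=10, cv_folds=5, rng_seed=0)
        res = gasvm.ga_optimize(X, y, cfg)
        grid_best = max(
            gasvm.kfold_cv_accuracy(X, y, gasvm.SVMSpec(C, g), k=5, seed=0)
            for C in np.logspace(-2, 2, 5)
            for g in np.logspace(-2, 2, 5)
        )
        assert res.best_fitness >= grid_best

    def test_mutation_stays_within_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            a = rng.uniform(0.01, 100.0)
            out = gasvm._mutate_gene(a, 0.01, 100.0, gen=1, gmax=10, rng=rng)
            assert 0.01 <= out <= 100.0
        # genes already at the bounds stay inside
        for a in (0.01, 100.0):
            for _ in range(50):
                out = gasvm._mutate_gene(a, 0.01, 100.0, gen=1, gmax=10, rng=rng)
                assert 0.01 <= out <= 100.0

    def test_best_within_bounds(self):
        X, y = blobs(40, sep=3.0)
        cfg = gasvm.GAConfig(population=6, generations=4, cv_folds=4, rng_seed=1)
        res = gasvm.ga_optimize(X, y, cfg)
        assert cfg.c_bounds[0] <= res.best.C <= cfg.c_bounds[1]
        assert cfg.g_bounds[0] <= res.best.g <= cfg.g_bounds[1]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            gasvm.GAConfig(population=1)
        with pytest.raises(ValueError):
            gasvm.GAConfig(c_bounds=(1.0, 0.5))
        with pytest.raises(ValueError):
            gasvm.GAConfig(g_bounds=(-1.0, 2.0))


class TestHierarchical:
    def test_default_feature_columns(self):
        assert gasvm.DEFAULT_FEATURE_COLS == ("reaction_time_s", "alpha_over_beta")

    def test_separated_levels_high_holdout_accuracy(self):
        table = level_table(80, seed=4)
        rng = np.random.default_rng(0)
        order = rng.permutation(len(table))
        train = table.iloc[order[:140]]
        test = table.iloc[order[140:]]
        cfg = gasvm.GAConfig(population=6, generations=5, cv_folds=5, rng_seed=0)
        model, details = gasvm.train_hierarchical(train, ga_cfg=cfg)
        acc = np.mean(gasvm.predict(model, test) == test["level"].to_numpy())
        assert acc >= 0.85
        assert set(details) >= {"stage1_spec", "stage2_spec", "stage1_ga", "stage2_ga"}

    def test_single_point_per_level_memorized(self):
        table = pd.DataFrame(
            {
                "reaction_time_s": [1.0, 1.5, 2.0],
                "alpha_over_beta": [0.5, 1.5, 3.0],
                "level": [1, 2, 3],
            }
        )
        model, _ = gasvm.train_hierarchical(
            table, specs=(gasvm.SVMSpec(1e4, 5.0), gasvm.SVMSpec(1e4, 5.0))
        )
        np.testing.assert_array_equal(gasvm.predict(model, table), [1, 2, 3])

    def test_missing_level_rejected(self):
        table = level_table(10)
        with pytest.raises(ValueError):
            gasvm.train_hierarchical(table[table["level"] != 2])

    def test_share_params_reuses_stage1(self):
        table = level_table(30)
        cfg = gasvm.GAConfig(population=4, generations=2, cv_folds=3, rng_seed=0)
        model, details = gasvm.train_hierarchical(table, ga_cfg=cfg, share_params=True)
        assert details["stage1_spec"] == details["stage2_spec"]

    def test_batch_equals_rowwise_prediction(self):
        table = level_table(20, seed=9)
        model, _ = gasvm.train_hierarchical(
            table, specs=(gasvm.SVMSpec(10, 1), gasvm.SVMSpec(10, 1))
        )
        X = table[list(model.feature_cols)].to_numpy()
        batch = gasvm.predict(model, X)
        rowwise = np.concatenate([gasvm.predict(model, row[None, :]) for row in X])
        np.testing.assert_array_equal(batch, rowwise)

    def test_prediction_deterministic(self):
        table = level_table(20, seed=2)
        model, _ = gasvm.train_hierarchical(
            table, specs=(gasvm.SVMSpec(10, 1), gasvm.SVMSpec(10, 1))
        )
        np.testing.assert_array_equal(
            gasvm.predict(model, table), gasvm.predict(model, table)
        )

    def test_schema_mismatch_rejected(self):
        table = level_table(15)
        model, _ = gasvm.train_hierarchical(
            table, specs=(gasvm.SVMSpec(10, 1), gasvm.SVMSpec(10, 1))
        )
        with pytest.raises(ValueError):
            gasvm.predict(model, table.drop(columns=["alpha_over_beta"]))
        with pytest.raises(ValueError):
            gasvm.predict(model, np.zeros((3, 5)))
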