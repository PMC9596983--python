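import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression

from vesseltort.cohort import make_cohort
from vesseltort.ml import (
    ISS_PREDICTOR_PRESET,
    BenchmarkConfig,
    BorderlineSmote,
    Standardizer,
    default_models,
    rfe,
    run_benchmark,
)


def small_model_set(seed):
    reg = default_models(seed)
    return {k: reg[k] for k in ("logistic", "svm")}


class TestStandardizer:
    def test_population_sd_closed_form(self):
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        out = Standardizer().fit_transform(X)
        np.testing.assert_allclose(out["x"], [-1.2247448, 0.0, 1.2247448], rtol=1e-6)

    def test_refit_transform_centers_fitting_data(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"x": rng.normal(5, 2, 100), "b": rng.integers(0, 2, 100)})
        sc = Standardizer().fit(X)
        out = sc.transform(X)
        assert abs(out["x"].mean()) < 1e-12
        assert out["b"].equals(X["b"])  # binary columns untouched

    def test_no_leakage_into_shifted_test_data(self):
        rng = np.random.default_rng(1)
        train = pd.DataFrame({"x": rng.normal(0, 1, 200)})
        test = pd.DataFrame({"x": rng.normal(3, 1, 200)})
        sc = Standardizer().fit(train)
        assert sc.transform(test)["x"].mean() > 2.0  # shift preserved

    def test_zero_sd_column_dropped_with_warning(self):
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0], "z": [7.0, 7.0, 7.0]})
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            out = Standardizer().fit_transform(X)
        assert "z" not in out.columns


class TestBorderlineSmote:
    def test_balanced_input_unchanged(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 3))
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        Xr, yr = BorderlineSmote(k=5, random_state=0).fit_resample(X, y)
        np.testing.assert_array_equal(Xr, X)
        np.testing.assert_array_equal(yr, y)

    def test_balances_exactly(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 1, (70, 4)), rng.normal(1.2, 1, (25, 4))])
        y = np.r_[np.zeros(70, int), np.ones(25, int)]
        _, yr = BorderlineSmote(k=5, random_state=1).fit_resample(X, y)
        counts = np.bincount(yr)
        assert counts[0] == counts[1]

    def test_noise_points_never_seed_synthesis(self):
        # two tight clusters far apart plus one isolated minority point deep
        # inside majority territory: that point is noise (all k neighbors
        # majority) and must not parent any synthetic sample
        rng = np.random.default_rng(2)
        maj = rng.normal(0, 0.3, (30, 2))
        minority = rng.normal(5, 0.3, (8, 2))
        noise_pt = np.array([[0.0, 0.1]])
        X = np.vstack([maj, minority, noise_pt])
        y = np.r_[np.zeros(30, int), np.ones(9, int)]
        sm = BorderlineSmote(k=5, random_state=3)
        sm.fit_resample(X, y)
        noise_index = len(X) - 1
        assert all(p != noise_index for p, _ in sm.parents_)

    def test_synthetic_points_between_their_parents(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = np.vstack([rng.normal(0, 1, (50, 3)), rng.normal(1.0, 1, (20, 3))])
            y = np.r_[np.zeros(50, int), np.ones(20, int)]
            sm = BorderlineSmote(k=5, random_state=seed)
            Xr, yr = sm.fit_resample(X, y)
            for i, (p, q) in enumerate(sm.parents_):
                z = Xr[len(X) + i]
                lo = np.minimum(X[p], X[q]) - 1e-12
                hi = np.maximum(X[p], X[q]) + 1e-12
                assert np.all(z >= lo) and np.all(z <= hi)

    def test_minority_too_small_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 2))
        y = np.r_[np.zeros(17, int), np.ones(3, int)]
        with pytest.raises(ValueError, match="k\\+1"):
            BorderlineSmote(k=5).fit_resample(X, y)


class TestRfe:
    def test_planted_features_recovered(self):
        hits = 0
        reps = 50
        for s in range(reps):
            rng = np.random.default_rng(s)
            X = pd.DataFrame(
                rng.normal(size=(1000, 10)),
                columns=[f"inf{i}" for i in range(5)] + [f"noise{i}" for i in range(5)],
            )
            beta = np.r_[np.full(5, 0.8), np.zeros(5)]
            p = 1 / (1 + np.exp(-(X.to_numpy() @ beta)))
            y = (rng.uniform(size=1000) < p).astype(int)
            sel = rfe(LogisticRegression(max_iter=2000), X, y, 5)
            hits += sum(c.startswith("inf") for c in sel) >= 4
        assert hits / reps >= 0.90

    def test_identity_when_target_is_feature_count(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        y = rng.integers(0, 2, 50)
        assert rfe(LogisticRegression(), X, y, 4) == list("abcd")
        with pytest.warns(RuntimeWarning, match="exceeds"):
            assert rfe(LogisticRegression(), X, y, 9) == list("abcd")

    def test_duplicated_column_resolved_by_column_order(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=300)
        b = rng.normal(size=300)
        X = pd.DataFrame({"a": a, "a_dup": a, "b": b})
        # each duplicate carries half the 'a' weight, so the tied pair sits
        # at the importance minimum and the tie-break must decide
        y = (0.6 * a + 2.0 * b + rng.normal(0, 0.5, 300) > 0).astype(int)
        # forcing a drop among the tied duplicates keeps the earlier column
        sel = rfe(LogisticRegression(max_iter=2000), X, y, 2)
        assert sel == ["a", "b"]


class TestRunBenchmark:
    def test_separable_outcome_reaches_perfect_test_auc(self):
        df = make_cohort(200, 0.355, coef={}, seed=4)
        df["iss"] = (df["max_curvature"] > df["max_curvature"].median()).astype(int)
        cfg = BenchmarkConfig(models=small_model_set(4), rfe_n_features=4, seed=4)
        reports, _ = run_benchmark(df, cfg, features=ISS_PREDICTOR_PRESET)
        assert max(r.test_auc for r in reports) == 1.0

    def test_label_permutation_null(self):
        df = make_cohort(400, 0.355, seed=6)
        rng = np.random.default_rng(6)
        df["iss"] = rng.permutation(df["iss"].to_numpy())
        cfg = BenchmarkConfig(models=small_model_set(6), seed=6)
        reports, _ = run_benchmark(df, cfg, features=ISS_PREDICTOR_PRESET + ["age", "bmi"])
        for r in reports:
            assert abs(r.test_auc - 0.5) <= 0.1, r.model

    def test_same_seed_bitwise_identical(self):
        df = make_cohort(150, 0.355, seed=9)
        cfg = BenchmarkConfig(models=small_model_set(9), seed=9)
        r1, p1 = run_benchmark(df, cfg, features=ISS_PREDICTOR_PRESET)
        r2, p2 = run_benchmark(df, cfg, features=ISS_PREDICTOR_PRESET)
        assert r1 == r2
        assert p1["selected_features"] == p2["selected_features"]

    def test_train_only_smote_never_uses_test_rows(self):
        df = make_cohort(150, 0.355, seed=10)
        cfg = BenchmarkConfig(models=small_model_set(10), seed=10)
        _, prov = run_benchmark(df, cfg, features=ISS_PREDICTOR_PRESET)
        assert prov["smote_parent_rows"], "expected synthetic samples"
        assert not set(prov["smote_parent_rows"]) & set(prov["test_rows"])

    def test_before_split_placement_runs(self):
        df = make_cohort(150, 0.355, seed=11)
        cfg = BenchmarkConfig(
            models=small_model_set(11), smote_placement="before_split", seed=11
        )
        reports, prov = run_benchmark(df, cfg, features=ISS_PREDICTOR_PRESET)
        assert prov["smote_placement"] == "before_split"
        assert all(0.0 <= r.test_auc <= 1.0 for r in reports)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            BenchmarkConfig(test_fraction=0.7)
        with pytest.raises(ValueError):
            BenchmarkConfig(cv_folds=1)
        with pytest.raises(ValueError):
            BenchmarkConfig(smote_placement="after")

    def test_single_model_rejected(self):
        df = make_cohort(100, 0.355, seed=0)
        reg = default_models(0)
        cfg = BenchmarkConfig(models={"logistic": reg["logistic"]}, seed=0)
        with pytest.raises(ValueError, match="2 model"):
            run_benchmark(df, cfg)
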