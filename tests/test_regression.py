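"""Feature extraction, least-squares age fit, per-decade evaluation."""

import numpy as np
import pytest

from paravae.regression import (AgeRegressionModel, FeatureMatrix, evaluate,
                                extract_features, fit_age_regression,
                                load_regression, predict_age, save_regression)
from paravae.vae import TrainedVAE, VAEConfig, init_params
from paravae.parallel import TrainedParallelVAE
from paravae.vae import LossWeights


@pytest.fixture(scope="module")
def untrained_pair():
    cfg = VAEConfig(image_side=32, n_latent=32)
    rng = np.random.default_rng(0)
    a = TrainedVAE(config=cfg, params=init_params(cfg, rng))
    b = TrainedVAE(config=cfg, params=init_params(cfg, rng))
    return TrainedParallelVAE(branch_a=a, branch_b=b, k=16,
                              weights=LossWeights.preset("loss1"))


class TestExtractFeatures:
    def test_parallel_mode_has_n_plus_k_columns(self, untrained_pair,
                                                tiny_records):
        fm = extract_features(untrained_pair, tiny_records[:4])
        assert fm.m == 32 + 16
        assert fm.column_origin.count("unique_a") == 16
        assert fm.column_origin.count("unique_b") == 16
        assert fm.column_origin.count("common") == 16

    def test_single_mode_has_n_columns_and_is_deterministic(self, tiny_records):
        cfg = VAEConfig(image_side=32, n_latent=32)
        model = TrainedVAE(config=cfg,
                           params=init_params(cfg, np.random.default_rng(1)))
        imgs = [r.image_a for r in tiny_records[:3]]
        fm1, fm2 = extract_features(model, imgs), extract_features(model, imgs)
        assert fm1.m == 32 and fm1.column_origin == ["latent"] * 32
        np.testing.assert_array_equal(fm1.X, fm2.X)

    def test_mode_mismatch_raises(self, untrained_pair, tiny_records):
        with pytest.raises(ValueError):
            extract_features(untrained_pair, [tiny_records[0].image_a])

    def test_common_block_is_mean_of_branch_halves(self, untrained_pair,
                                                   tiny_records):
        fm_mean = extract_features(untrained_pair, tiny_records[:2])
        fm_a = extract_features(untrained_pair, tiny_records[:2], common="branch_a")
        # branch-a-only common differs from the symmetric mean on an untrained pair
        assert not np.allclose(fm_mean.X[:, 32:], fm_a.X[:, 32:])


class TestFit:
    def test_recovers_exact_linear_relation(self):
        ages = np.linspace(15, 75, 30)
        X = FeatureMatrix(X=(ages - 30)[:, None], column_origin=["latent"],
                          mode="single")
        model = fit_age_regression(X, ages)
        assert model.beta[0] == pytest.approx(1.0, abs=1e-8)
        assert model.alpha == pytest.approx(30.0, abs=1e-8)

    def test_constant_target_under_ridge(self):
        rng = np.random.default_rng(3)
        X = FeatureMatrix(X=rng.normal(size=(20, 4)),
                          column_origin=["latent"] * 4, mode="single")
        model = fit_age_regression(X, np.full(20, 42.0), solver="ridge",
                                   ridge_lambda=1.0)
        np.testing.assert_allclose(model.beta, 0.0, atol=1e-10)
        assert model.alpha == pytest.approx(42.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        A = rng.normal(size=(60, 5))
        ages = 40 + A @ rng.normal(size=5) * 3 + rng.normal(size=60) * 0.1
        X = FeatureMatrix(X=A, column_origin=["latent"] * 5, mode="single")
        model = fit_age_regression(X, ages)
        # brute-force centered normal equations
        Ac = A - A.mean(axis=0)
        yc = ages - ages.mean()
        beta_ne = np.linalg.solve(Ac.T @ Ac, Ac.T @ yc)
        np.testing.assert_allclose(model.beta, beta_ne, rtol=1e-8)

    def test_training_fit_beats_mean_age_baseline(self):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(50, 6))
        ages = rng.uniform(10, 79, size=50)
        X = FeatureMatrix(X=A, column_origin=["latent"] * 6, mode="single")
        model = fit_age_regression(X, ages)
        pred = predict_age(model, X)
        assert np.mean((pred - ages) ** 2) <= np.var(ages) + 1e-12

    def test_degenerate_design_rejected(self):
        X = FeatureMatrix(X=np.zeros((0, 3)), column_origin=["latent"] * 3,
                          mode="single")
        with pytest.raises(ValueError):
            fit_age_regression(X, [])


class TestPredict:
    def test_zero_beta_returns_intercept(self):
        model = AgeRegressionModel(beta=np.zeros(3), alpha=40.0,
                                   feature_layout=["latent"] * 3)
        np.testing.assert_allclose(predict_age(model, np.eye(3)), 40.0)

    def test_unit_vector_probe(self):
        model = AgeRegressionModel(beta=np.array([5.0, 0.0, 0.0]), alpha=0.0,
                                   feature_layout=["latent"] * 3)
        assert predict_age(model, np.eye(3))[0] == pytest.approx(5.0)

    def test_matches_dot_product_loop(self):
        rng = np.random.default_rng(6)
        beta = rng.normal(size=7)
        model = AgeRegressionModel(beta=beta, alpha=12.3,
                                   feature_layout=["latent"] * 7)
        A = rng.normal(size=(9, 7))
        loop = [sum(b * x for b, x in zip(beta, row)) + 12.3 for row in A]
        np.testing.assert_allclose(predict_age(model, A), loop, rtol=1e-12)

    def test_layout_mismatch_raises(self):
        model = AgeRegressionModel(beta=np.zeros(2), alpha=0.0,
                                   feature_layout=["latent"] * 2)
        fm = FeatureMatrix(X=np.zeros((1, 2)), column_origin=["common"] * 2,
                           mode="parallel")
        with pytest.raises(ValueError):
            predict_age(model, fm)


class TestEvaluate:
    def test_hand_computed_statistics(self):
        true = np.array([30.0, 31.0, 32.0])
        pred = true + np.array([1.0, 2.0, 10.0])
        report = evaluate(pred, true)
        row = report[report["age_range"] == "30-39"].iloc[0]
        assert row["median_abs_error"] == pytest.approx(2.0)
        assert row["mean_abs_error"] == pytest.approx(13.0 / 3)

    def test_perfect_predictions(self):
        true = np.array([15.0, 25.0, 75.0])
        report = evaluate(true, true)
        assert (report.loc[report["n"] > 0, "median_abs_error"] == 0).all()

    def test_single_subject_grouping_and_row_structure(self):
        report = evaluate(np.array([39.0]), np.array([35.0]))
        assert len(report) == 8
        assert list(report["age_range"])[:2] == ["10-19", "20-29"]
        row = report[report["age_range"] == "30-39"].iloc[0]
        assert row["n"] == 1 and row["median_abs_error"] == pytest.approx(4.0)
        empty = report[report["age_range"] == "20-29"].iloc[0]
        assert empty["n"] == 0 and np.isnan(empty["median_abs_error"])

    def test_decade_boundaries_are_closed(self):
        report = evaluate(np.array([19.0, 20.0]), np.array([19.0, 20.0]))
        assert report[report["age_range"] == "10-19"]["n"].iloc[0] == 1
        assert report[report["age_range"] == "20-29"]["n"].iloc[0] == 1

    def test_permutation_invariance(self):
        rng = np.random.default_rng(8)
        true = rng.uniform(10, 79, 40)
        pred = true + rng.normal(size=40) * 5
        perm = rng.permutation(40)
        r1 = evaluate(pred, true)
        r2 = evaluate(pred[perm], true[perm])
        for col in ("n", "median_abs_error", "mean_abs_error"):
            np.testing.assert_allclose(r1[col], r2[col])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            evaluate([], [])


def test_regression_json_round_trip(tmp_path):
    model = AgeRegressionModel(beta=np.array([1.5, -2.0]), alpha=44.0,
                               feature_layout=["unique_a", "common"],
                               solver="ridge", ridge_lambda=2.0)
    path = tmp_path / "reg.json"
    save_regression(model, path)
    loaded = load_regression(path)
    np.testing.assert_array_equal(loaded.beta, model.beta)
    assert loaded.alpha == model.alpha
    assert loaded.feature_layout == model.feature_layout
    assert loaded.solver == "ridge" and loaded.ridge_lambda == 2.0
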