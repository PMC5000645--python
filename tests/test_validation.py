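"""Validation battery: LOO, Y-randomization, outliers, external criteria, AD."""

import numpy as np
import pandas as pd
import pytest

from kocqspr.subset_mlr import fit_mlr
from kocqspr.validation import (
    count_outliers,
    external_criteria,
    external_stats,
    leverage_ad,
    loo_cv,
    loo_cv_hat,
    max_pairwise_correlation,
    validate_model,
    warning_leverage,
    y_randomization,
)


class TestLooCv:
    def test_exact_linear_data_perfect(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 3))
        y = 1.0 + X @ np.array([1.0, 2.0, -1.0])
        r2, rms, _ = loo_cv(X, y)
        assert r2 == pytest.approx(1.0, abs=1e-10)
        assert rms == pytest.approx(0.0, abs=1e-8)

    def test_hat_shortcut_equals_naive_refits(self, fixture_93x4):
        X, y = fixture_93x4
        r2_a, rms_a, pred_a = loo_cv(X, y)
        r2_b, rms_b, pred_b = loo_cv_hat(X, y)
        assert r2_a == pytest.approx(r2_b, abs=1e-10)
        assert rms_a == pytest.approx(rms_b, abs=1e-10)
        assert np.allclose(pred_a, pred_b, atol=1e-10)

    def test_duplicated_rows_stay_finite(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((10, 2))
        X = np.vstack([X, X])
        y = np.concatenate([np.arange(10.0)] * 2)
        r2, rms, preds = loo_cv(X, y)
        assert np.isfinite([r2, rms]).all() and np.isfinite(preds).all()

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="n >= d"):
            loo_cv(np.zeros((4, 2)), np.zeros(4))


class TestYRandomization:
    def test_strong_signal_passes(self, fixture_93x4):
        X, y = fixture_93x4
        mean_rms, all_rms, passed = y_randomization(X, y, n_cases=200, seed=0)
        assert passed
        assert len(all_rms) == 200
        m = fit_mlr(X, y)
        assert mean_rms > m.rms_train

    def test_pure_noise_reported_honestly(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((50, 3))
        y = rng.standard_normal(50)
        mean_rms, _, _ = y_randomization(X, y, n_cases=100, seed=1)
        true_rms = fit_mlr(X, y).rms_train
        assert mean_rms == pytest.approx(true_rms, rel=0.15)

    def test_seed_reproducible_and_seed_stable(self, fixture_93x4):
        X, y = fixture_93x4
        _, a, _ = y_randomization(X, y, n_cases=50, seed=3)
        _, b, _ = y_randomization(X, y, n_cases=50, seed=3)
        assert np.array_equal(a, b)
        m1, c1, _ = y_randomization(X, y, n_cases=200, seed=4)
        m2, c2, _ = y_randomization(X, y, n_cases=200, seed=5)
        pooled_se = np.sqrt(c1.var() / 200 + c2.var() / 200)
        assert abs(m1 - m2) < 3 * pooled_se


class TestOutliersAndRijmax:
    def test_exact_fit_has_no_outliers(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((20, 2))
        y = X @ np.array([1.0, 1.0])
        assert count_outliers(fit_mlr(X, y), X, y) == 0

    def test_injected_gross_outlier_counted(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((60, 2))
        y = X @ np.array([1.0, -1.0]) + rng.normal(0, 0.1, 60)
        m = fit_mlr(X, y)
        y2 = y.copy()
        y2[7] += 10 * m.rms_train
        m2 = fit_mlr(X, y2)
        assert count_outliers(m2, X, y2, k=2.5) == 1
        assert count_outliers(m2, X, y2, k=1e9) == 0

    def test_rijmax_extremes_and_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(40)
        assert max_pairwise_correlation(np.column_stack([x, x])) \
            == pytest.approx(1.0, abs=1e-12)
        q = np.column_stack([np.cos(np.linspace(0, 2 * np.pi, 40)),
                             np.sin(np.linspace(0, 2 * np.pi, 40))])
        q -= q.mean(axis=0)
        assert max_pairwise_correlation(q) < 0.05
        X4 = rng.standard_normal((40, 4))
        oracle = max(
            np.corrcoef(X4[:, i], X4[:, j])[0, 1] ** 2
            for i in range(4) for j in range(i + 1, 4)
        )
        assert max_pairwise_correlation(X4) == pytest.approx(oracle, abs=1e-12)
        with pytest.raises(ValueError):
            max_pairwise_correlation(x[:, None])


class TestExternalStats:
    def test_training_partition_reproduces_training_stats(self, fixture_93x4):
        X, y = fixture_93x4
        m = fit_mlr(X, y)
        r2, rms, _ = external_stats(m, X, y)
        assert rms == pytest.approx(m.rms_train, abs=1e-12)
        assert r2 == pytest.approx(m.r2_train, abs=1e-10)

    def test_constant_test_property_raises_but_names_rms(self, fixture_93x4):
        X, y = fixture_93x4
        m = fit_mlr(X, y)
        with pytest.raises(ValueError, match="constant"):
            external_stats(m, X.iloc[:5], np.full(5, 2.0))

    def test_matches_hand_computation(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((30, 2))
        y = X @ np.array([1.0, 2.0]) + rng.normal(0, 0.3, 30)
        m = fit_mlr(X, y)
        Xt = rng.standard_normal((10, 2))
        yt = Xt @ np.array([1.0, 2.0]) + rng.normal(0, 0.3, 10)
        r2, rms, pred = external_stats(m, Xt, yt)
        assert rms == pytest.approx(np.sqrt(np.mean((yt - pred) ** 2)), rel=1e-12)
        assert r2 == pytest.approx(np.corrcoef(pred, yt)[0, 1] ** 2, rel=1e-12)


class TestExternalCriteria:
    def _fit(self, seed=7, sigma=0.2):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((60, 3))
        y = 0.5 + X @ np.array([1.0, -0.8, 0.6]) + rng.normal(0, sigma, 60)
        Xt = rng.standard_normal((30, 3))
        yt = 0.5 + Xt @ np.array([1.0, -0.8, 0.6]) + rng.normal(0, sigma, 30)
        return fit_mlr(X, y), X, y, Xt, yt

    def test_near_perfect_predictions_hit_ideal_values(self):
        m, X, y, Xt, yt = self._fit(sigma=1e-9)
        crit = external_criteria(m, X, y, Xt, yt)
        for name in ("q2_f1", "q2_f2", "q2_f3", "ccc", "k", "k_prime"):
            assert crit[name] == pytest.approx(1.0, abs=1e-4)
        assert crit["abs_r20_diff"] == pytest.approx(0.0, abs=1e-6)

    def test_mean_only_model_fails_q2f2(self):
        from kocqspr.subset_mlr import LinearModel

        m, X, y, Xt, yt = self._fit()
        mean_only = LinearModel(
            descriptor_names=("x0",), coefficients=np.array([0.0]),
            intercept=float(y.mean()), n_train=len(y),
            r2_train=0.0, rms_train=float(y.std()), s_train=float(y.std()),
        )
        crit = external_criteria(mean_only, X[:, :1], y, Xt[:, :1], yt)
        assert crit["q2_f2"] <= 0

    def test_matches_formula_by_formula_oracle(self):
        m, X, y, Xt, yt = self._fit()
        crit = external_criteria(m, X, y, Xt, yt)
        pred = m.predict(Xt)
        assert crit["q2_f1"] == pytest.approx(
            1 - ((yt - pred) ** 2).sum() / ((yt - y.mean()) ** 2).sum(), rel=1e-12)
        assert crit["q2_f2"] == pytest.approx(
            1 - ((yt - pred) ** 2).sum() / ((yt - yt.mean()) ** 2).sum(), rel=1e-12)
        assert crit["q2_f3"] == pytest.approx(
            1 - (((yt - pred) ** 2).mean()) / ((y - y.mean()) ** 2).mean(), rel=1e-12)
        num = 2 * ((yt - yt.mean()) * (pred - pred.mean())).sum()
        den = (((yt - yt.mean()) ** 2).sum() + ((pred - pred.mean()) ** 2).sum()
               + len(yt) * (yt.mean() - pred.mean()) ** 2)
        assert crit["ccc"] == pytest.approx(num / den, rel=1e-12)
        assert crit["k"] == pytest.approx((yt * pred).sum() / (pred ** 2).sum(),
                                          rel=1e-12)


class TestLeverageAd:
    def test_warning_leverage_for_published_geometry(self):
        # three descriptors, 93 training compounds
        assert warning_leverage(3, 93) == pytest.approx(0.129, abs=5e-4)
        assert round(warning_leverage(3, 93), 2) == 0.13

    def test_training_leverages_sum_to_d_plus_1(self, fixture_93x4):
        X, _ = fixture_93x4
        X3 = X[["a", "b", "c"]]
        rep = leverage_ad(X3, X3)
        assert rep.leverages.sum() == pytest.approx(4.0, abs=1e-9)
        assert ((rep.leverages >= 1 / len(X3) - 1e-12)
                & (rep.leverages <= 1.0 + 1e-12)).all()

    def test_centroid_query_has_minimum_leverage(self):
        rng = np.random.default_rng(8)
        Xt = rng.standard_normal((50, 3))
        rep = leverage_ad(Xt, Xt.mean(axis=0)[None, :])
        assert rep.leverages.iloc[0] == pytest.approx(1 / 50, abs=1e-12)

    def test_outside_ad_flags_match_threshold(self):
        rng = np.random.default_rng(9)
        Xt = rng.standard_normal((40, 2))
        Xq = np.vstack([Xt[:5], Xt[:1] + 50.0])  # one gross extrapolation
        rep = leverage_ad(Xt, Xq, query_ids=[f"q{i}" for i in range(6)])
        assert rep.outside_ad == ["q5"]
        assert set(rep.outside_ad) == {
            i for i, h in rep.leverages.items() if h > rep.h_star
        }

    def test_singular_training_design_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="singular|rank"):
            leverage_ad(np.column_stack([x, 2 * x]), np.zeros((1, 2)))


class TestValidateModel:
    def test_full_battery_coherent(self, fixture_93x4):
        X, y = fixture_93x4
        rng = np.random.default_rng(10)
        Xt = pd.DataFrame(rng.standard_normal((30, 4)), columns=list("abcd"))
        yt = 1.0 + Xt.to_numpy() @ np.array([0.8, -1.2, 0.5, 0.3]) \
            + rng.normal(0, 0.4, 30)
        m = fit_mlr(X, y)
        rep = validate_model(m, X, y, Xt, yt, n_rand_cases=100, seed=0)
        assert rep.y_rand_pass
        assert rep.rms_rand_mean > rep.rms_train
        assert 0 <= rep.rij_max <= 1
        assert rep.o2_5 >= 0
        assert rep.external_criteria["q2_f1"] > 0.7
        r2_loo_naive, rms_loo_naive, _ = loo_cv(X, y)
        assert rep.r2_loo == pytest.approx(r2_loo_naive, abs=1e-10)
        assert rep.rms_loo == pytest.approx(rms_loo_naive, abs=1e-10)
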