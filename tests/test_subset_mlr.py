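"""OLS subset regression and the Replacement Method search."""

import numpy as np
import pandas as pd
import pytest

from kocqspr.descriptor_pool import DescriptorMatrix
from kocqspr.subset_mlr import (
    dimension_sweep,
    exhaustive_search,
    fit_mlr,
    rm_search,
)
from kocqspr.synthetic_data import SyntheticSpec, gen_planted_linear


class TestFitMlr:
    def test_exact_linear_data(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((20, 3))
        y = 2.0 + X @ np.array([1.0, -0.5, 3.0])
        m = fit_mlr(X, y)
        assert m.r2_train == pytest.approx(1.0, abs=1e-12)
        assert m.rms_train == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(m.coefficients, [1.0, -0.5, 3.0])

    def test_orthogonal_noise_gives_near_zero_fit(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((500, 2))
        y = rng.standard_normal(500)
        m = fit_mlr(X, y)
        assert abs(m.coefficients).max() < 0.2
        assert m.r2_train < 0.05

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((10, 2))
        y = rng.standard_normal(10)
        m = fit_mlr(X, y)
        A = np.column_stack([np.ones(10), X])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        assert np.allclose([m.intercept, *m.coefficients], beta, atol=1e-10)

    def test_matches_statsmodels(self, fixture_93x4):
        import statsmodels.api as sm

        X, y = fixture_93x4
        m = fit_mlr(X, y)
        sm_fit = sm.OLS(y, sm.add_constant(X.to_numpy())).fit()
        assert np.allclose([m.intercept, *m.coefficients], sm_fit.params, atol=1e-9)
        assert np.allclose(m.coef_se, sm_fit.bse[1:], atol=1e-9)
        assert m.s_train == pytest.approx(np.sqrt(sm_fit.mse_resid), abs=1e-9)

    def test_rms_and_s_denominators(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((30, 4))
        y = X @ np.array([1, 1, 1, 1.0]) + rng.standard_normal(30)
        m = fit_mlr(X, y)
        resid2 = m.rms_train ** 2 * 30
        assert m.s_train == pytest.approx(np.sqrt(resid2 / (30 - 4 - 1)), rel=1e-10)

    def test_row_permutation_invariance(self, fixture_93x4):
        X, y = fixture_93x4
        perm = np.random.default_rng(4).permutation(len(y))
        m1 = fit_mlr(X, y)
        m2 = fit_mlr(X.iloc[perm], y[perm])
        assert np.allclose(m1.coefficients, m2.coefficients, atol=1e-10)

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(20)
        X = pd.DataFrame({"a": x, "b": 2 * x, "c": rng.standard_normal(20)})
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_mlr(X, rng.standard_normal(20))

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="rows"):
            fit_mlr(np.zeros((3, 3)), np.zeros(3))


class TestRmSearch:
    def test_finds_planted_subset(self, planted_pool):
        matrix, y, spec = planted_pool
        y_train = y[matrix.split_labels == "train"].to_numpy()
        res = rm_search(matrix, y_train, d=2, n_restarts=5, seed=1)
        truth = {matrix.descriptor_names[j] for j in spec.true_subset}
        assert set(res.model.descriptor_names) == truth

    def test_d_equal_pool_size_returns_full_model(self):
        spec = SyntheticSpec(n_train=40, n_test=0, n_descriptors=5,
                             true_subset=(0, 1), beta=(1.0, 1.0),
                             sigma=0.1, seed=3)
        m, y = gen_planted_linear(spec)
        res = rm_search(m, y.to_numpy(), d=5, n_restarts=1, seed=0)
        assert set(res.model.descriptor_names) == set(m.descriptor_names)

    def test_d1_equals_argmin_scan(self, planted_pool):
        matrix, y, _ = planted_pool
        y_train = y[matrix.split_labels == "train"].to_numpy()
        res = rm_search(matrix, y_train, d=1, n_restarts=5, seed=2)
        X = matrix.train_rows()
        scan = min(
            (fit_mlr(X[[c]], y_train).s_train, c) for c in X.columns
        )
        assert res.model.descriptor_names == (scan[1],)
        assert res.model.s_train == pytest.approx(scan[0], rel=1e-12)

    def test_accepted_steps_strictly_decrease_s(self, planted_pool):
        matrix, y, _ = planted_pool
        y_train = y[matrix.split_labels == "train"].to_numpy()
        res = rm_search(matrix, y_train, d=3, n_restarts=4, seed=5)
        assert all(res.converged)
        for _, grp in res.step_log.groupby("restart"):
            s = grp["s_train"].to_numpy()
            assert (np.diff(s) < 0).all()

    def test_matches_exhaustive_on_small_pools(self):
        hits = 0
        for seed in range(8):
            spec = SyntheticSpec(n_train=60, n_test=0, n_descriptors=12,
                                 true_subset=(2, 9), beta=(1.0, -1.5),
                                 sigma=0.01, seed=seed)
            m, y = gen_planted_linear(spec)
            yt = y.to_numpy()
            rm = rm_search(m, yt, d=2, n_restarts=10, seed=seed)
            ex = exhaustive_search(m, yt, d=2)
            assert rm.model.s_train >= ex.s_train - 1e-12
            hits += set(rm.model.descriptor_names) == set(ex.descriptor_names)
        assert hits == 8

    def test_noise_column_never_hurts(self, planted_pool):
        matrix, y, _ = planted_pool
        y_train = y[matrix.split_labels == "train"].to_numpy()
        base = rm_search(matrix, y_train, d=2, n_restarts=5, seed=6)
        rng = np.random.default_rng(99)
        bigger = DescriptorMatrix(
            values=matrix.values.assign(purenoise=rng.standard_normal(
                len(matrix.values))),
            split_labels=matrix.split_labels,
        )
        res = rm_search(bigger, y_train, d=2, n_restarts=5, seed=6)
        assert res.model.s_train <= base.model.s_train + 1e-12

    def test_invalid_d_rejected(self, planted_pool):
        matrix, y, _ = planted_pool
        y_train = y[matrix.split_labels == "train"].to_numpy()
        with pytest.raises(ValueError, match="exceeds pool"):
            rm_search(matrix, y_train, d=100)


class TestExhaustiveSearch:
    def test_evaluates_all_subsets(self):
        spec = SyntheticSpec(n_train=30, n_test=0, n_descriptors=6,
                             true_subset=(0, 4), beta=(1.0, 1.0),
                             sigma=0.05, seed=20)
        m, y = gen_planted_linear(spec)
        best = exhaustive_search(m, y.to_numpy(), d=2)
        # literal double-loop re-implementation
        X = m.train_rows()
        oracle = min(
            (fit_mlr(X[[a, b]], y.to_numpy()).s_train, (a, b))
            for i, a in enumerate(X.columns)
            for b in list(X.columns)[i + 1:]
        )
        assert set(best.descriptor_names) == set(oracle[1])

    def test_exact_fit_subset_returns_zero_s(self):
        spec = SyntheticSpec(n_train=30, n_test=0, n_descriptors=8,
                             true_subset=(1, 5), beta=(2.0, -1.0),
                             sigma=0.0, seed=21)
        m, y = gen_planted_linear(spec)
        best = exhaustive_search(m, y.to_numpy(), d=2)
        assert set(best.descriptor_names) == {"desc001", "desc005"}
        assert best.s_train == pytest.approx(0.0, abs=1e-10)

    def test_cap_enforced(self):
        spec = SyntheticSpec(n_train=30, n_test=0, n_descriptors=40,
                             true_subset=(0,), beta=(1.0,), sigma=0.1, seed=22)
        m, y = gen_planted_linear(spec)
        with pytest.raises(ValueError, match="cap"):
            exhaustive_search(m, y.to_numpy(), d=4, cap=1000)


class TestDimensionSweep:
    def test_planted_truth_selects_d2(self, planted_pool):
        matrix, y, _ = planted_pool
        tr = matrix.split_labels == "train"
        table = dimension_sweep(
            matrix, y[tr].to_numpy(), y[~tr].to_numpy(),
            d_range=range(1, 5), n_restarts=5, seed=0, margin=0.01,
        )
        assert (np.diff(table["rms_train"]) <= 1e-9).all()  # nested models
        assert table.loc[table["selected"], "d"].iloc[0] == 2

    def test_restart_count_irrelevant_on_small_pool(self, planted_pool):
        matrix, y, _ = planted_pool
        tr = matrix.split_labels == "train"
        t1 = dimension_sweep(matrix, y[tr].to_numpy(), y[~tr].to_numpy(),
                             d_range=[2], n_restarts=1, seed=0)
        t10 = dimension_sweep(matrix, y[tr].to_numpy(), y[~tr].to_numpy(),
                              d_range=[2], n_restarts=10, seed=0)
        assert t1["descriptors"].iloc[0] == t10["descriptors"].iloc[0]
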