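import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from facecue import (
    PowerSpec,
    bf_against_null,
    jzs_bf,
    pearson,
    required_n,
    standardized_ols,
    winsorize,
)
from oracles import (
    jzs_bf_grid,
    jzs_effect_bf_grid,
    normal_equations_betas,
    required_n_scan,
)


class TestWinsorize:
    def test_inliers_unchanged(self, rng):
        x = rng.uniform(-1, 1, 50)
        np.testing.assert_array_equal(winsorize(x), x)

    def test_constant_vector_unchanged(self):
        x = np.full(10, 3.0)
        np.testing.assert_array_equal(winsorize(x), x)

    def test_outlier_clipped_to_original_moments(self, rng):
        x = np.concatenate([rng.standard_normal(20), [10.0]])
        expected_cap = x.mean() + 3 * x.std(ddof=1)  # ORIGINAL moments
        out = winsorize(x)
        assert out[-1] == pytest.approx(expected_cap)
        np.testing.assert_array_equal(out[:-1], x[:-1])

    def test_missing_values_pass_through(self):
        x = np.array([0.0, 1.0, np.nan, 2.0, 50.0])
        out = winsorize(x)
        assert np.isnan(out[2])
        assert np.isfinite(out[[0, 1, 3, 4]]).all()

    def test_ranks_of_unclipped_preserved(self, rng):
        x = rng.standard_normal(100)
        out = winsorize(x, k=1.0)
        inner = np.abs((x - x.mean()) / x.std(ddof=1)) < 1.0
        assert np.all(
            np.argsort(x[inner], kind="stable")
            == np.argsort(out[inner], kind="stable")
        )


class TestPearson:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        r, df, p = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert df == 8

    def test_orthogonal_vectors(self):
        x = np.array([-1, 1, -1, 1.0])
        y = np.array([1, 1, -1, -1.0])  # centered, orthogonal to x
        r, _, p = pearson(x, y)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_textbook_formula_oracle(self, rng):
        x = rng.standard_normal(10)
        y = 0.5 * x + rng.standard_normal(10)
        r, df, p = pearson(x, y)
        cov = ((x - x.mean()) * (y - y.mean())).sum() / 9
        r_oracle = cov / (x.std(ddof=1) * y.std(ddof=1))
        assert r == pytest.approx(r_oracle, abs=1e-12)
        t = r_oracle * np.sqrt(df / (1 - r_oracle**2))
        assert p == pytest.approx(2 * sps.t.sf(abs(t), df), abs=1e-12)

    def test_pairwise_complete_cases(self):
        x = np.array([1, 2, 3, np.nan, 5.0, 6.0])
        y = np.array([2, 4, 6, 8.0, np.nan, 12.0])
        r, df, _ = pearson(x, y)
        assert df == 2  # 4 complete pairs
        assert r == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson([1, 1, 1], [1, 2, 3])


class TestStandardizedOLS:
    def test_single_predictor_beta_equals_r(self, rng):
        x = rng.standard_normal(40)
        y = 0.6 * x + rng.standard_normal(40)
        res = standardized_ols(y, pd.DataFrame({"x": x}))
        r, _, p = pearson(x, y)
        assert res[0].beta == pytest.approx(r, abs=1e-10)
        assert res[0].p == pytest.approx(p, abs=1e-10)
        assert abs(res[0].beta) <= 1 + 1e-9

    def test_matches_normal_equations_oracle(self, rng):
        n = 12
        X = rng.standard_normal((n, 2))
        y = 0.5 * X[:, 0] - 0.3 * X[:, 1] + rng.standard_normal(n)
        res = standardized_ols(y, pd.DataFrame(X, columns=["a", "b"]))
        oracle = normal_equations_betas(y, X)
        np.testing.assert_allclose([r.beta for r in res], oracle, atol=1e-10)
        assert res[0].df == n - 3
        for r in res:
            assert np.sign(r.beta) == np.sign(r.t)
            assert 0 < r.p <= 1

    def test_exact_predictor_plus_orthogonal(self):
        x1 = np.array([1, 2, 3, 4, 5, 6, 7, 8.0])
        x2 = np.array([1, -1, 1, -1, 1, -1, 1, -1.0])  # orthogonal to centered x1
        res = standardized_ols(x1, pd.DataFrame({"x1": x1, "x2": x2}))
        assert res[0].beta == pytest.approx(1.0, abs=1e-10)
        assert res[1].beta == pytest.approx(0.0, abs=1e-10)

    def test_collinear_design_rejected(self, rng):
        x = rng.standard_normal(20)
        with pytest.raises(ValueError, match="rank-deficient"):
            standardized_ols(
                rng.standard_normal(20), pd.DataFrame({"a": x, "b": 2 * x})
            )

    def test_listwise_deletion(self, rng):
        x = rng.standard_normal(30)
        y = x + rng.standard_normal(30)
        y[3] = np.nan
        res = standardized_ols(y, pd.DataFrame({"x": x}))
        assert res[0].n == 29


class TestJZSBayesFactor:
    def test_null_predictor_gives_evidence_for_null(self, rng):
        n = 259
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)  # unrelated
        bf = jzs_bf(y, pd.DataFrame({"x": x}), "x")
        assert bf < 1

    def test_matches_fine_grid_quadrature_oracle(self, rng):
        # a spread of R^2 / n / p combinations
        for r2, n, p in [(0.01, 50, 1), (0.1, 100, 2), (0.3, 259, 2),
                         (0.001, 259, 1), (0.5, 30, 3)]:
            ours = bf_against_null(r2, n, p)
            oracle = jzs_bf_grid(r2, n, p)
            assert ours == pytest.approx(oracle, rel=1e-3), (r2, n, p)

    def test_effect_bf_matches_oracle_on_toy_regression(self, rng):
        n = 40
        X = rng.standard_normal((n, 2))
        y = 0.4 * X[:, 0] + rng.standard_normal(n)
        ours = jzs_bf(y, pd.DataFrame(X, columns=["a", "b"]), "a")
        oracle = jzs_effect_bf_grid(y, X, 0)
        assert ours == pytest.approx(oracle, rel=1e-3)

    def test_strong_effect_large_and_monotone_in_n(self, rng):
        x = rng.standard_normal(400)
        y = 0.5 * x + np.sqrt(1 - 0.25) * rng.standard_normal(400)
        bfs = []
        for n in (100, 200, 400):
            bfs.append(jzs_bf(y[:n], pd.DataFrame({"x": x[:n]}), "x"))
        assert bfs[0] > 100
        assert bfs[0] < bfs[1] < bfs[2]

    def test_bf_decreasing_in_p_for_fixed_n(self, rng):
        """For one model family and n, BF10 is a monotone decreasing
        function of the p value across datasets."""
        n = 60
        rows = []
        for _ in range(40):
            x = rng.standard_normal(n)
            y = rng.uniform(-0.5, 0.5) * x + rng.standard_normal(n)
            res = standardized_ols(y, pd.DataFrame({"x": x}))[0]
            bf = jzs_bf(y, pd.DataFrame({"x": x}), "x")
            rows.append((res.p, bf))
        rows.sort()
        bfs = [b for _, b in rows]
        assert all(b1 >= b2 for b1, b2 in zip(bfs, bfs[1:]))

    def test_unknown_focal_rejected(self, rng):
        with pytest.raises(KeyError):
            jzs_bf(rng.standard_normal(20),
                   pd.DataFrame({"x": rng.standard_normal(20)}), "z")


class TestRequiredN:
    def test_small_effect_sample_size(self):
        spec = PowerSpec(f2=0.027, power=0.80, alpha=0.05, df1=1, n_predictors=2)
        assert required_n(spec) == 293

    def test_larger_effects_need_fewer_cases(self):
        small = required_n(PowerSpec(f2=0.027))
        medium = required_n(PowerSpec(f2=0.15))
        assert medium < small

    def test_matches_exhaustive_scan_oracle(self):
        spec = PowerSpec(f2=0.15, power=0.80, alpha=0.05, df1=1, n_predictors=1)
        assert required_n(spec) == required_n_scan(0.15, n_predictors=1)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PowerSpec(f2=-1)
        with pytest.raises(ValueError):
            PowerSpec(f2=0.1, alpha=1.5)
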