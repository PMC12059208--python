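import numpy as np
import pandas as pd
import pytest

from divscape.assoc import (
    correlation_matrix,
    cv_select_lambda,
    lambda_max,
    lasso_fit,
    max_genetic_env_correlation,
    per_species_analysis,
    significance_label,
    univariate_ols,
)
from divscape.errors import ZeroVarianceError


@pytest.fixture
def xy_tables(rng):
    n = 40
    env = pd.DataFrame(rng.normal(size=(n, 5)), columns=list("abcde"))
    div = pd.DataFrame({
        "Hs": 0.5 * env["a"] + rng.normal(scale=0.5, size=n),
        "rarity": rng.normal(size=n),
    })
    return div, env


class TestCorrelationMatrix:
    def test_unit_diagonal_and_symmetry(self, xy_tables):
        corr = correlation_matrix(*xy_tables)
        np.testing.assert_allclose(np.diag(corr), 1.0)
        np.testing.assert_allclose(corr.to_numpy(), corr.to_numpy().T, atol=1e-14)
        assert (corr.abs().to_numpy() <= 1 + 1e-12).all()

    def test_self_and_antisymmetric(self, rng):
        v = rng.normal(size=30)
        div = pd.DataFrame({"Hs": v, "rarity": -v})
        env = pd.DataFrame({"a": v})
        corr = correlation_matrix(div, env)
        assert corr.loc["Hs", "a"] == pytest.approx(1.0)
        assert corr.loc["rarity", "a"] == pytest.approx(-1.0)

    def test_zero_variance_column_gives_nan(self, xy_tables, caplog):
        div, env = xy_tables
        env = env.assign(const=1.0)
        corr = correlation_matrix(div, env)
        assert np.isnan(corr.loc["Hs", "const"])

    def test_pairwise_complete(self, xy_tables):
        div, env = xy_tables
        env2 = env.copy()
        env2.loc[:4, "b"] = np.nan
        corr = correlation_matrix(div, env2)
        expected = div["Hs"][5:].corr(env2["b"][5:])
        assert corr.loc["Hs", "b"] == pytest.approx(expected)

    def test_max_genetic_env_entry(self, xy_tables):
        corr = correlation_matrix(*xy_tables)
        sub = corr.loc[["Hs", "rarity"], list("abcde")].abs()
        assert max_genetic_env_correlation(corr) == pytest.approx(
            sub.max().max())

    def test_misaligned_rows_rejected(self, xy_tables):
        div, env = xy_tables
        with pytest.raises(ValueError):
            correlation_matrix(div.iloc[:-1], env)


@pytest.fixture
def orthonormal_design():
    # Hadamard-derived +-1 columns: zero mean, unit population sd,
    # X'X = n I under the 1/n inner product
    H = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float)
    X = pd.DataFrame(H, columns=list("abc"))
    beta = np.array([1.0, 0.5, -0.2])
    return X, H @ beta, beta


class TestLassoFit:
    def test_all_zero_at_lambda_max(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 6)))
        y = rng.normal(size=30)
        lmax = lambda_max(X, y)
        path = lasso_fit(X, y, lambdas=np.array([lmax * 1.001, lmax]))
        np.testing.assert_array_equal(path.coefficients, 0.0)

    def test_soft_threshold_oracle(self, orthonormal_design):
        X, y, beta = orthonormal_design
        for lam in (0.3, 0.6, 1.2):
            path = lasso_fit(X, y, lambdas=np.array([lam]))
            expected = np.sign(beta) * np.maximum(np.abs(beta) - lam, 0.0)
            np.testing.assert_allclose(path.coefficients[0], expected, atol=1e-8)

    def test_lambda_zero_equals_ols(self, rng):
        X = pd.DataFrame(rng.normal(size=(25, 4)), columns=list("abcd"))
        y = rng.normal(size=25)
        path = lasso_fit(X, y, lambdas=np.array([0.0]))
        Z = np.column_stack([np.ones(25), X.to_numpy()])
        ols, *_ = np.linalg.lstsq(Z, y, rcond=None)
        np.testing.assert_allclose(path.coefficients[0], ols[1:], atol=1e-8)
        assert path.intercepts[0] == pytest.approx(ols[0], abs=1e-8)

    def test_support_monotone_along_path(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 8)))
        y = rng.normal(size=60)
        path = lasso_fit(X, y)
        nnz = (path.coefficients != 0.0).sum(axis=1)  # lambdas descending
        # as lambda grows the support never grows (ties allowed)
        assert (np.diff(nnz[::-1]) <= 0).all()

    def test_frac_var_explained_non_increasing_in_lambda(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 6)))
        y = X.iloc[:, 0].to_numpy() + rng.normal(scale=0.5, size=50)
        path = lasso_fit(X, y)
        Xm = X.to_numpy()
        rss = [np.sum((y - (Xm @ c + b)) ** 2)
               for c, b in zip(path.coefficients, path.intercepts)]
        frac = 1 - np.asarray(rss) / np.sum((y - y.mean()) ** 2)
        # lambdas descend: frac must be non-increasing when lambda grows
        assert (np.diff(frac[::-1]) <= 1e-10).all()

    def test_back_transform_scale(self, rng):
        # shrinking a predictor's units by 1000x inflates its coefficient
        n = 50
        x = rng.normal(size=n)
        y = x + rng.normal(scale=0.1, size=n)
        lam = np.array([0.05])
        big = lasso_fit(pd.DataFrame({"x": x}), y, lambdas=lam)
        small = lasso_fit(pd.DataFrame({"x": x / 1000}), y, lambdas=lam)
        assert small.coefficients[0, 0] == pytest.approx(
            1000 * big.coefficients[0, 0], rel=1e-9)

    def test_constant_response_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 2)))
        with pytest.raises(ZeroVarianceError):
            lasso_fit(X, np.ones(10))


class TestCVSelectLambda:
    def test_null_selects_sparse_model_near_lambda_max(self, rng):
        hits = []
        for r in range(5):
            local = np.random.default_rng(r)
            X = pd.DataFrame(local.normal(size=(60, 10)))
            y = local.normal(size=60)
            res = cv_select_lambda(X, y, folds=60)
            hits.append(res.n_nonzero)
            assert res.lambda_opt >= res.lambda_grid[-1]
        assert np.median(hits) <= 3

    def test_recovers_single_true_predictor(self, rng):
        n = 80
        X = pd.DataFrame(rng.normal(size=(n, 6)), columns=list("abcdef"))
        y = 2.0 * X["c"].to_numpy() + rng.normal(scale=0.3, size=n)
        res = cv_select_lambda(X, y, folds=n)
        assert res.coefficients["c"] != 0.0
        assert res.best_predictor() == "c"
        assert res.coefficients["c"] == pytest.approx(2.0, abs=0.1)
        assert res.frac_var_explained > 0.9

    def test_loo_is_deterministic(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 4)))
        y = rng.normal(size=30)
        a = cv_select_lambda(X, y, folds=1000, seed=1)
        b = cv_select_lambda(X, y, folds=1000, seed=99)
        assert a.lambda_opt == b.lambda_opt
        assert a.n_folds == b.n_folds == 30
        pd.testing.assert_series_equal(a.coefficients, b.coefficients)

    def test_too_few_rows_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.raises(ValueError):
            cv_select_lambda(X, np.array([1.0, 2.0]))

    def test_missing_rows_dropped(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        y = X["a"].to_numpy() + rng.normal(scale=0.2, size=40)
        X.loc[0, "b"] = np.nan
        res = cv_select_lambda(X, y, folds=10, seed=0)
        assert res.n_obs == 39


class TestUnivariateOLS:
    def test_perfect_fit(self):
        x = np.arange(10.0)
        res = univariate_ols(3 * x + 1, x)
        assert res.slope == pytest.approx(3.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_hand_closed_form(self):
        res = univariate_ols([0.0, 1.0, 1.0], [0.0, 1.0, 2.0])
        assert res.slope == pytest.approx(0.5)
        assert res.intercept == pytest.approx(1 / 6)
        assert res.r_squared == pytest.approx(0.75)

    def test_r2_equals_squared_pearson(self, rng):
        for _ in range(5):
            x = rng.normal(size=25)
            y = 0.3 * x + rng.normal(size=25)
            res = univariate_ols(y, x)
            r = np.corrcoef(x, y)[0, 1]
            assert res.r_squared == pytest.approx(r**2, abs=1e-12)

    def test_p_value_matches_t_distribution(self, rng):
        from scipy import stats
        x = rng.normal(size=20)
        y = 0.5 * x + rng.normal(size=20)
        res = univariate_ols(y, x)
        # reconstruct two-sided t test with n-2 df
        n = 20
        r = np.sqrt(res.r_squared) * np.sign(res.slope)
        t = r * np.sqrt((n - 2) / (1 - r**2))
        assert res.p_value == pytest.approx(
            2 * stats.t.sf(abs(t), n - 2), abs=1e-12)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ZeroVarianceError):
            univariate_ols([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])

    def test_complete_pairs_only(self):
        y = [1.0, np.nan, 3.0, 4.0, 2.0]
        x = [1.0, 2.0, 3.0, np.nan, 0.5]
        res = univariate_ols(y, x)
        assert res.n == 3


class TestPerSpecies:
    def make_tables(self, rng, sizes):
        rows = []
        for sp, n in sizes.items():
            x = rng.normal(size=n)
            rows.append(pd.DataFrame({
                "species": sp,
                "Hs": 0.3 * x + rng.normal(scale=0.5, size=n),
                "rarity": rng.normal(size=n),
                "pcurv": x,
            }))
        return pd.concat(rows, ignore_index=True)

    def test_all_below_threshold_empty_map(self, rng):
        tables = self.make_tables(rng, {"s1": 10, "s2": 20})
        assert per_species_analysis(tables, "pcurv") == {}

    def test_strictly_greater_than_threshold(self, rng):
        tables = self.make_tables(rng, {"s1": 20, "s2": 21, "s3": 40})
        out = per_species_analysis(tables, "pcurv")
        assert set(out) == {"s2", "s3"}
        assert set(out["s3"]) == {"Hs", "rarity"}
        assert out["s3"]["Hs"].n == 40

    def test_matches_direct_fit(self, rng):
        tables = self.make_tables(rng, {"s1": 30})
        out = per_species_analysis(tables, "pcurv")
        direct = univariate_ols(tables["Hs"], tables["pcurv"])
        assert out["s1"]["Hs"].r_squared == pytest.approx(direct.r_squared)


def test_significance_labels():
    assert significance_label(0.01) == "significant"
    assert significance_label(0.07) == "marginally significant"
    assert significance_label(0.5) == "not significant"
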