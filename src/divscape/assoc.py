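"""Association models: correlation screen, LASSO with CV, univariate OLS.

The LASSO minimizes

    (1 / (2n)) * sum_i (y_i - b0 - x_i' b)^2 + lambda * sum_j |b_j|

by coordinate descent on internally standardized predictors (zero mean, unit
population standard deviation); coefficients are reported back on the
original predictor scale, which is why tiny-scale predictors (e.g. terrain
curvatures in radians/m) can carry large printed coefficients. The penalty
grid runs from lambda_max = max_j |<x_j_std, y - ybar>| / n down a log-spaced
grid. Cross-validation caps the fold count at n, so a very large requested
fold count degrades to deterministic leave-one-out.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import lasso_path as _sk_lasso_path
from sklearn.model_selection import KFold

from .errors import ConvergenceError, ZeroVarianceError

logger = logging.getLogger(__name__)

GENETIC_INDICES = ("Hs", "rarity")


# ---------------------------------------------------------------------------
# correlation screen

def correlation_matrix(
    div: pd.DataFrame,
    env: pd.DataFrame,
    min_periods: int = 3,
) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations among genetic + environmental columns.

    ``div`` and ``env`` must be row-aligned. Non-numeric columns are ignored;
    zero-variance columns yield NaN entries with a warning. The diagonal is 1
    wherever defined.
    """
    if len(div) != len(env):
        raise ValueError("diversity and environment tables are not row-aligned")
    joint = pd.concat(
        [div.reset_index(drop=True), env.reset_index(drop=True)], axis=1
    ).select_dtypes(include=[np.number])
    joint = joint.loc[:, ~joint.columns.duplicated()]
    for col in joint.columns:
        x = joint[col].dropna()
        if len(x) >= 2 and np.isclose(x.std(ddof=0), 0.0):
            logger.warning("column %r has zero variance; correlations undefined", col)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = joint.corr(method="pearson", min_periods=min_periods)
    return corr


def max_genetic_env_correlation(corr: pd.DataFrame) -> float:
    """Largest |r| between a genetic index and any environmental column."""
    gen = [c for c in GENETIC_INDICES if c in corr.index]
    env = [c for c in corr.columns if c not in GENETIC_INDICES]
    if not gen or not env:
        raise ValueError("correlation matrix lacks genetic or environmental columns")
    return float(corr.loc[gen, env].abs().max().max())


# ---------------------------------------------------------------------------
# LASSO

@dataclass
class LassoPath:
    """Coefficient path on the original predictor scale."""

    predictors: list[str]
    lambdas: np.ndarray              # descending
    coefficients: np.ndarray         # (n_lambdas, n_predictors), original scale
    intercepts: np.ndarray           # (n_lambdas,)

    def coef_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.coefficients, columns=self.predictors)
        df.insert(0, "lambda", self.lambdas)
        df.insert(1, "intercept", self.intercepts)
        return df


@dataclass
class LassoResult:
    """CV-selected LASSO fit summary."""

    predictors: list[str]
    lambda_grid: np.ndarray
    cv_error: np.ndarray
    lambda_opt: float
    coefficients: pd.Series          # original scale, indexed by predictor
    intercept: float
    std_coefficients: pd.Series      # on the standardized predictor scale
    n_nonzero: int
    frac_var_explained: float
    n_folds: int
    n_obs: int

    @property
    def nonzero(self) -> pd.Series:
        return self.coefficients[self.coefficients != 0.0]

    def best_predictor(self) -> str:
        """Nonzero predictor with the largest absolute standardized coefficient."""
        nz = self.std_coefficients[self.coefficients != 0.0]
        if nz.empty:
            raise ValueError("no nonzero predictor at the selected lambda")
        return str(nz.abs().idxmax())


def first_active_predictor(path: LassoPath) -> str:
    """First predictor to enter the path as the penalty relaxes from lambda_max."""
    active = np.flatnonzero((path.coefficients != 0.0).any(axis=1))
    if active.size == 0:
        raise ValueError("no predictor enters the path on this grid")
    for i in range(len(path.lambdas)):
        nz = np.flatnonzero(path.coefficients[i] != 0.0)
        if nz.size:
            order = np.argsort(-np.abs(path.coefficients[i, nz]))
            return path.predictors[nz[order[0]]]
    raise AssertionError("unreachable")


def _clean_xy(X: pd.DataFrame, y) -> tuple[pd.DataFrame, np.ndarray]:
    y = pd.Series(np.asarray(y, dtype=float), index=X.index)
    mask = X.notna().all(axis=1) & y.notna()
    dropped = int((~mask).sum())
    if dropped:
        logger.info("dropping %d rows with missing predictor/response values", dropped)
    return X.loc[mask], y.loc[mask].to_numpy()


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population sd (ddof=0), glmnet-style
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd_safe, mean, sd_safe


def lambda_max(X: pd.DataFrame, y) -> float:
    """Smallest penalty at which every slope coefficient is exactly zero."""
    X, y = _clean_xy(X, y)
    Xs, _, _ = _standardize(X.to_numpy(dtype=float))
    r = y - y.mean()
    return float(np.max(np.abs(Xs.T @ r)) / len(y))


def _make_lambda_grid(lmax: float, grid_size: int, lambda_min_ratio: float) -> np.ndarray:
    return np.geomspace(lmax, lmax * lambda_min_ratio, grid_size)


def _path_standardized(
    Xs: np.ndarray, y: np.ndarray, lambdas: np.ndarray
) -> np.ndarray:
    """Slope coefficients on the standardized scale at each lambda (desc)."""
    yc = y - y.mean()
    # tight tolerance first; p ~ n problems can stall a hair above it, in
    # which case one retry at a still-strict tolerance is accepted
    for tol in (1e-5, 1e-3, 1e-2):
        if tol > 1e-5:
            logger.debug("retrying coordinate descent at tol=%g", tol)
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=UserWarning)
            try:
                _, coefs, _ = _sk_lasso_path(
                    Xs, yc, alphas=lambdas, max_iter=100_000, tol=tol
                )
                return coefs.T  # (n_lambdas, n_predictors)
            except UserWarning as exc:
                last = exc
    raise ConvergenceError(
        f"coordinate descent failed to converge on the penalty grid: {last}"
    )


def lasso_fit(
    X: pd.DataFrame,
    y,
    grid_size: int = 100,
    lambda_min_ratio: float = 1e-4,
    lambdas: np.ndarray | None = None,
) -> LassoPath:
    """Fit the full LASSO coefficient path.

    Rows with missing values are dropped first. Coefficients come back on the
    original predictor scale; intercepts absorb the centring.
    """
    X, y = _clean_xy(X, y)
    if len(y) < 2:
        raise ValueError("need at least 2 complete rows")
    if np.isclose(np.std(y), 0.0):
        raise ZeroVarianceError("constant response")
    Xmat = X.to_numpy(dtype=float)
    Xs, mean, sd = _standardize(Xmat)
    if lambdas is None:
        lmax = float(np.max(np.abs(Xs.T @ (y - y.mean()))) / len(y))
        lambdas = _make_lambda_grid(lmax, grid_size, lambda_min_ratio)
    lambdas = np.asarray(lambdas, dtype=float)
    coefs_std = np.empty((len(lambdas), Xs.shape[1]))
    pos = lambdas > 0
    if pos.any():
        coefs_std[pos] = _path_standardized(Xs, y, lambdas[pos])
    if (~pos).any():
        # lambda = 0 is plain least squares on the standardized design
        beta0, *_ = np.linalg.lstsq(Xs, y - y.mean(), rcond=None)
        coefs_std[~pos] = beta0
    coefs = coefs_std / sd
    intercepts = y.mean() - coefs @ mean
    return LassoPath(
        predictors=list(X.columns),
        lambdas=lambdas,
        coefficients=coefs,
        intercepts=intercepts,
    )


def cv_select_lambda(
    X: pd.DataFrame,
    y,
    folds: int = 1000,
    grid_size: int = 100,
    lambda_min_ratio: float = 1e-4,
    seed: int | None = None,
) -> LassoResult:
    """Select the penalty by cross-validation on a shared lambda grid.

    The effective fold count is ``min(folds, n)``; at ``folds >= n`` this is
    leave-one-out, which needs no shuffling and is fully deterministic. Ties
    in mean CV squared error are broken toward the larger lambda (sparser
    model). ``frac_var_explained`` is 1 - RSS/TSS of the full-data fit at the
    selected lambda.
    """
    X, y = _clean_xy(X, y)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 complete rows for cross-validation")
    if np.isclose(np.std(y), 0.0):
        raise ZeroVarianceError("constant response")
    Xmat = X.to_numpy(dtype=float)
    Xs_full, _, _ = _standardize(Xmat)
    lmax = float(np.max(np.abs(Xs_full.T @ (y - y.mean()))) / n)
    grid = _make_lambda_grid(lmax, grid_size, lambda_min_ratio)

    k = min(folds, n)
    if k == n:
        fold_indices = [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)]
    else:
        kf = KFold(n_splits=k, shuffle=True, random_state=seed)
        fold_indices = list(kf.split(Xmat))

    sq_err = np.zeros((len(grid), n))
    for train, test in fold_indices:
        Xtr, ytr = Xmat[train], y[train]
        Xs, mean, sd = _standardize(Xtr)
        coefs_std = _path_standardized(Xs, ytr, grid)
        coefs = coefs_std / sd
        intercepts = ytr.mean() - coefs @ mean
        pred = Xmat[test] @ coefs.T + intercepts  # (n_test, n_lambdas)
        sq_err[:, test] = ((pred - y[test][:, None]) ** 2).T
    cv_error = sq_err.mean(axis=1)
    # grid is descending, argmin returns the first (largest-lambda) minimum
    opt_idx = int(np.argmin(cv_error))
    lambda_opt = float(grid[opt_idx])

    path = lasso_fit(X, y, lambdas=grid)
    coef = pd.Series(path.coefficients[opt_idx], index=path.predictors)
    intercept = float(path.intercepts[opt_idx])
    sd_full = Xmat.std(axis=0)
    std_coef = pd.Series(coef.to_numpy() * np.where(sd_full > 0, sd_full, 1.0),
                         index=path.predictors)
    resid = y - (Xmat @ coef.to_numpy() + intercept)
    tss = float(np.sum((y - y.mean()) ** 2))
    frac = float(np.clip(1.0 - np.sum(resid**2) / tss, 0.0, 1.0))
    return LassoResult(
        predictors=list(X.columns),
        lambda_grid=grid,
        cv_error=cv_error,
        lambda_opt=lambda_opt,
        coefficients=coef,
        intercept=intercept,
        std_coefficients=std_coef,
        n_nonzero=int((coef != 0.0).sum()),
        frac_var_explained=frac,
        n_folds=k,
        n_obs=n,
    )


# ---------------------------------------------------------------------------
# univariate follow-up

@dataclass
class OLSResult:
    """Simple linear regression summary (two-sided t test on the slope)."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def univariate_ols(y, x) -> OLSResult:
    """Least-squares fit of ``y ~ x`` on complete pairs.

    r^2 equals the squared Pearson correlation; the p-value is the two-sided
    t test on the slope with n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.isclose(np.std(x), 0.0):
        raise ZeroVarianceError("constant predictor")
    fit = stats.linregress(x, y)
    return OLSResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=int(len(x)),
    )


def per_species_analysis(
    tables: pd.DataFrame,
    predictor: str,
    min_populations: int = 20,
    responses: tuple[str, ...] = GENETIC_INDICES,
) -> dict[str, dict[str, OLSResult]]:
    """Independent univariate regressions for species with > ``min_populations``.

    ``tables`` is a pooled frame with columns species, the responses and the
    predictor (one row per population). Species at or below the population
    threshold are excluded; the result may be empty. No multiple-testing
    correction is applied across species.
    """
    out: dict[str, dict[str, OLSResult]] = {}
    for species, df in tables.groupby("species", sort=True):
        if len(df) <= min_populations:
            continue
        res: dict[str, OLSResult] = {}
        for response in responses:
            res[response] = univariate_ols(df[response], df[predictor])
        out[str(species)] = res
    return out


def significance_label(p: float) -> str:
    if p < 0.05:
        return "significant"
    if p < 0.10:
        return "marginally significant"
    return "not significant"
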