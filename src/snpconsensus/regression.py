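"""Regression ensemble over the forest-selected SNPs.

Three methods vote on the same top-k design: forward stepwise OLS
(partial-F entry, Wald reporting), ridge regression at an automatically
chosen penalty (generalised cross-validation), and the lasso at the
10-fold cross-validation-optimal penalty with sequential partial-F
screening of the nonzero set.  All methods treat genotype codes 1/2/3 as
numeric additive predictors and flag SNPs at p <= 0.01 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

SIGNIFICANCE_CUTOFF = 0.01
STEPWISE_ENTRY_ALPHA = 0.05
DEFAULT_CV_FOLDS = 10

REGRESSION_METHODS = ("stepwise", "ridge", "lasso")
ALL_METHODS = REGRESSION_METHODS + ("boruta",)


@dataclass
class MethodCall:
    """One method's verdict on one predictor in one iteration.

    ``statistic`` is a p-value for the regression methods and a mean
    Z-score for Boruta.
    """

    method: str
    snp_id: str
    statistic: float
    significant: bool
    iteration_index: int
    is_covariate: bool = False


@dataclass
class RegressionFit:
    method: str
    names: list[str]
    coefficients: np.ndarray
    intercept: float
    lambda_: float | None
    rss: float
    model_r2: float
    model_pvalue: float | None
    std_errors: np.ndarray | None
    df_model: int
    n: int

    @property
    def df_resid(self) -> float:
        return self.n - self.df_model - 1


def wald_test(beta: float, se: float, df: float) -> float:
    """Two-sided p-value of beta/se against Student's t with ``df`` dof."""
    if se <= 0:
        raise ValueError("standard error must be > 0")
    if df <= 0:
        raise ValueError("residual degrees of freedom must be > 0")
    return float(2.0 * stats.t.sf(abs(beta / se), df))


def _with_intercept(x: np.ndarray) -> np.ndarray:
    return np.hstack([np.ones((x.shape[0], 1)), x])


def _rss_lstsq(x: np.ndarray, y: np.ndarray) -> float:
    """RSS of an intercept-plus-x least squares fit (rank tolerant)."""
    xi = _with_intercept(x) if x.size else np.ones((y.size, 1))
    beta, _, _, _ = np.linalg.lstsq(xi, y, rcond=None)
    return float(np.sum((y - xi @ beta) ** 2))


def ols_fit(x: np.ndarray, y: np.ndarray, names: list[str] | None = None
            ) -> RegressionFit:
    """Ordinary least squares via the normal equations, with Wald SEs."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.ndim != 2 or x.shape[0] != y.size:
        raise ValueError("x must be (n, p) matching len(y)")
    n, p = x.shape
    names = names if names is not None else [f"x{j}" for j in range(p)]
    xi = _with_intercept(x)
    if np.linalg.matrix_rank(xi) < p + 1:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    xtx_inv = np.linalg.inv(xi.T @ xi)
    beta = xtx_inv @ xi.T @ y
    resid = y - xi @ beta
    rss = float(resid @ resid)
    df_resid = n - p - 1
    sigma2 = rss / df_resid if df_resid > 0 else np.nan
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / ss_tot if ss_tot > 0 else 0.0
    if p > 0 and df_resid > 0 and ss_tot > 0 and rss > 0:
        f = (ss_tot - rss) / p / (rss / df_resid)
        model_p = float(stats.f.sf(f, p, df_resid))
    else:
        model_p = None
    return RegressionFit(
        method="ols", names=list(names), coefficients=beta[1:],
        intercept=float(beta[0]), lambda_=None, rss=rss, model_r2=r2,
        model_pvalue=model_p, std_errors=se[1:], df_model=p, n=n,
    )


def partial_f_test(fit_small: RegressionFit, fit_large: RegressionFit,
                   n: int) -> float:
    """Upper-tail p of the nested-model F statistic.

    F = ((RSS_s - RSS_l)/Δdf) / (RSS_l/(n - df_l - 1)).
    """
    if not set(fit_small.names) <= set(fit_large.names):
        raise ValueError("models are not nested")
    delta_df = fit_large.df_model - fit_small.df_model
    if delta_df == 0:
        return 1.0  # identical predictor sets: zero numerator by definition
    if delta_df < 0:
        raise ValueError("larger model must add predictors")
    df_resid = n - fit_large.df_model - 1
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom in the larger model")
    num = max(fit_small.rss - fit_large.rss, 0.0) / delta_df
    if fit_large.rss <= 0:
        return 0.0 if num > 0 else 1.0
    f = num / (fit_large.rss / df_resid)
    return float(stats.f.sf(f, delta_df, df_resid))


def _partial_f_p(rss_small: float, rss_large: float, delta_df: int,
                 df_resid: float) -> float:
    if df_resid <= 0:
        return 1.0
    num = max(rss_small - rss_large, 0.0) / delta_df
    if rss_large <= 0:
        return 0.0 if num > 0 else 1.0
    return float(stats.f.sf(num / (rss_large / df_resid), delta_df, df_resid))


def stepwise_forward(x: np.ndarray, y: np.ndarray, names: list[str],
                     entry_alpha: float = STEPWISE_ENTRY_ALPHA,
                     cutoff: float = SIGNIFICANCE_CUTOFF,
                     iteration_index: int = 1,
                     covariate_names: set[str] | None = None,
                     ) -> tuple[RegressionFit | None, list[MethodCall]]:
    """Greedy forward selection from the null model.

    At each step the candidate with the largest RSS reduction enters if
    its partial-F entry p-value passes ``entry_alpha``; reported per-SNP
    p-values come from Wald tests on the final selected model.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    n, p = x.shape
    covariate_names = covariate_names or set()
    selected: list[int] = []
    rss_current = _rss_lstsq(x[:, :0], y)
    remaining = list(range(p))
    while remaining and len(selected) < n - 2:
        if rss_current <= 1e-12:
            break
        best_j, best_rss = None, None
        for j in remaining:
            rss_j = _rss_lstsq(x[:, selected + [j]], y)
            if best_rss is None or rss_j < best_rss:
                best_j, best_rss = j, rss_j
        df_resid = n - (len(selected) + 1) - 1
        p_enter = _partial_f_p(rss_current, best_rss, 1, df_resid)
        if p_enter > entry_alpha:
            break
        selected.append(best_j)
        remaining.remove(best_j)
        rss_current = best_rss
    if not selected:
        return None, []
    sel_names = [names[j] for j in selected]
    fit = ols_fit(x[:, selected], y, sel_names)
    fit.method = "stepwise"
    calls = []
    for i, name in enumerate(sel_names):
        pval = wald_test(float(fit.coefficients[i]), float(fit.std_errors[i]),
                         fit.df_resid)
        calls.append(MethodCall(
            method="stepwise", snp_id=name, statistic=pval,
            significant=pval <= cutoff, iteration_index=iteration_index,
            is_covariate=name in covariate_names,
        ))
    return fit, calls


DEFAULT_RIDGE_GRID = tuple(np.logspace(-3, 5, 161))


def ridge_fit(x: np.ndarray, y: np.ndarray, names: list[str] | None = None,
              lambda_: float | None = None,
              lambda_grid: tuple[float, ...] = DEFAULT_RIDGE_GRID,
              cutoff: float = SIGNIFICANCE_CUTOFF,
              iteration_index: int = 1,
              covariate_names: set[str] | None = None,
              ) -> tuple[RegressionFit, list[MethodCall]]:
    """Ridge regression with an unpenalised intercept.

    The penalty is chosen by minimising generalised cross-validation
    error over ``lambda_grid`` unless ``lambda_`` is given explicitly
    (``lambda_=0`` reproduces OLS).  Per-SNP Wald p-values use the
    sandwich variance sigma^2 (X'X+lI)^-1 X'X (X'X+lI)^-1 on centred
    predictors.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    n, p = x.shape
    names = names if names is not None else [f"x{j}" for j in range(p)]
    covariate_names = covariate_names or set()
    x_mean = x.mean(axis=0)
    y_mean = y.mean()
    xc = x - x_mean
    yc = y - y_mean
    u, d, vt = np.linalg.svd(xc, full_matrices=False)
    uty = u.T @ yc
    if lambda_ is None:
        best_gcv, lambda_ = np.inf, float(lambda_grid[0])
        for lam in lambda_grid:
            shrink = d**2 / (d**2 + lam)
            fitted = u @ (shrink * uty)
            rss = float(np.sum((yc - fitted) ** 2))
            edf = float(shrink.sum()) + 1.0  # +1 for the intercept
            gcv = n * rss / (n - edf) ** 2
            if gcv < best_gcv:
                best_gcv, lambda_ = gcv, float(lam)
    shrink = d / (d**2 + lambda_)
    beta = vt.T @ (shrink * uty)
    fitted = xc @ beta
    resid = yc - fitted
    rss = float(resid @ resid)
    edf = float((d**2 / (d**2 + lambda_)).sum()) + 1.0
    df_resid = max(n - edf, 1.0)
    sigma2 = rss / df_resid
    # sandwich variance of the ridge coefficients
    a_inv_vt = vt.T * (1.0 / (d**2 + lambda_))
    cov = sigma2 * (a_inv_vt * d**2) @ a_inv_vt.T
    se = np.sqrt(np.maximum(np.diag(cov), 1e-300))
    ss_tot = float(yc @ yc)
    r2 = 1.0 - rss / ss_tot if ss_tot > 0 else 0.0
    fit = RegressionFit(
        method="ridge", names=list(names), coefficients=beta,
        intercept=float(y_mean - x_mean @ beta), lambda_=lambda_, rss=rss,
        model_r2=r2, model_pvalue=None, std_errors=se,
        df_model=p, n=n,
    )
    calls = []
    for i, name in enumerate(names):
        pval = wald_test(float(beta[i]), float(se[i]), df_resid)
        calls.append(MethodCall(
            method="ridge", snp_id=name, statistic=pval,
            significant=pval <= cutoff, iteration_index=iteration_index,
            is_covariate=name in covariate_names,
        ))
    return fit, calls


def lasso_fit(x: np.ndarray, y: np.ndarray, names: list[str] | None = None,
              n_folds: int = DEFAULT_CV_FOLDS, seed: int = 0,
              cutoff: float = SIGNIFICANCE_CUTOFF,
              iteration_index: int = 1,
              covariate_names: set[str] | None = None,
              lambda_: float | None = None,
              ) -> tuple[RegressionFit, list[MethodCall]]:
    """Lasso at the CV-minimising penalty, with partial-F screening.

    Predictors are standardised internally (glmnet convention) and the
    penalty grid's CV-error minimiser is used, unless ``lambda_`` fixes
    the penalty directly (on the standardised scale, in the
    1/(2n)-normalised objective).  Nonzero-coefficient SNPs are then
    tested largest-|standardised beta| first, each by a partial F-test
    against the model of previously accepted SNPs; acceptance requires
    p <= ``cutoff``.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    n, p = x.shape
    names = names if names is not None else [f"x{j}" for j in range(p)]
    covariate_names = covariate_names or set()
    sd = x.std(axis=0)
    keep = sd > 0
    xs = np.zeros_like(x)
    xs[:, keep] = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    if lambda_ is not None:
        model = Lasso(alpha=lambda_, max_iter=50_000).fit(xs, y)
        model.alpha_ = lambda_
    else:
        if n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        cv = KFold(n_splits=min(n_folds, n), shuffle=True, random_state=seed)
        model = LassoCV(cv=cv, max_iter=50_000).fit(xs, y)
    beta_std = model.coef_
    beta = np.zeros(p)
    beta[keep] = beta_std[keep] / sd[keep]
    fitted = model.predict(xs)
    rss = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    nonzero = np.nonzero(beta_std)[0]
    fit = RegressionFit(
        method="lasso", names=list(names), coefficients=beta,
        intercept=float(model.intercept_ - x.mean(axis=0) @ beta),
        lambda_=float(model.alpha_), rss=rss,
        model_r2=1.0 - rss / ss_tot if ss_tot > 0 else 0.0,
        model_pvalue=None, std_errors=None,
        df_model=int(nonzero.size), n=n,
    )
    order = nonzero[np.argsort(-np.abs(beta_std[nonzero]), kind="stable")]
    calls = []
    accepted: list[int] = []
    rss_base = _rss_lstsq(x[:, :0], y)
    for j in order:
        rss_with = _rss_lstsq(x[:, accepted + [int(j)]], y)
        df_resid = n - (len(accepted) + 1) - 1
        pval = _partial_f_p(rss_base, rss_with, 1, df_resid)
        significant = pval <= cutoff
        calls.append(MethodCall(
            method="lasso", snp_id=names[j], statistic=pval,
            significant=significant, iteration_index=iteration_index,
            is_covariate=names[j] in covariate_names,
        ))
        if significant:
            accepted.append(int(j))
            rss_base = rss_with
    return fit, calls
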