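"""Uniform fitting and term-level Wald tests for linear predictor models.

``fit_model`` returns maximum-likelihood estimates for linear (OLS),
logistic, and Cox models through a single :class:`FittedModel` interface.
The linear path solves the centered normal equations directly: the
resampling and simulation engines refit the same design tens of thousands
of times, and a lean solver keeps those loops fast (tests assert agreement
with statsmodels OLS to 1e-8 relative error).  Logistic models are fitted
with statsmodels ``Logit`` (Newton), Cox models with statsmodels ``PHReg``
using the Efron tie correction.

Term-level tests follow the Wald construction: for a single-column term the
statistic is z = beta/se, referred to a t distribution (linear) or standard
normal (logistic/Cox); a multi-column term uses the quadratic-form Wald
statistic with an F reference (linear) or chi-square (otherwise).  A
likelihood-ratio alternative is available through the selection module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, special, stats

from .data import Dataset
from .exceptions import FitError, SeparationError, SingularDesignError

MAX_ITER = 100
LOGLIK_TOL = 1e-9


@dataclass
class FittedModel:
    """One fitted model: coefficients, SEs, covariance, log-likelihood, AIC.

    ``params``/``bse``/``cov`` cover the covariate columns only; the
    intercept (linear/logistic) is stored separately since it never takes
    part in selection.  ``aic = -2*loglik + 2*(number of estimated
    regression coefficients)``; the log-likelihood is the partial
    log-likelihood for Cox models.
    """

    family: str
    columns: tuple
    term_map: dict = field(repr=False)
    params: np.ndarray
    bse: np.ndarray
    cov: np.ndarray = field(repr=False)
    loglik: float
    aic: float
    nobs: int
    converged: bool = True
    intercept: float | None = None
    intercept_se: float | None = None
    df_resid: int | None = None

    @property
    def terms(self) -> tuple:
        return tuple(self.term_map)

    def coef(self, column: str) -> float:
        return float(self.params[self.columns.index(column)])

    def se(self, column: str) -> float:
        return float(self.bse[self.columns.index(column)])


def fit_model(data: Dataset, included_terms=None) -> FittedModel:
    """Fit the model containing ``included_terms`` (default: all terms).

    Raises :class:`SingularDesignError` for rank-deficient designs and
    :class:`SeparationError` for logistic separation; non-convergence within
    ``MAX_ITER`` iterations is flagged on the returned model.
    """
    if included_terms is None:
        terms = data.term_names
    else:
        unknown = set(included_terms) - set(data.term_names)
        if unknown:
            raise KeyError(f"unknown terms: {sorted(unknown)}")
        keep = set(included_terms)
        terms = tuple(t for t in data.term_names if t in keep)
    col_idx = ([int(i) for t in terms for i in data.terms[t]]
               if terms else [])
    p = len(col_idx)
    n_coef = p + (1 if data.family in ("linear", "logistic") else 0)
    if data.n < n_coef + 1 + (1 if data.family != "cox" else 0):
        raise FitError(f"too few observations (N={data.n}) to fit "
                       f"{n_coef} coefficients")
    X = data.X[:, col_idx]
    columns = tuple(data.columns[i] for i in col_idx)
    term_map, pos = {}, 0
    for t in terms:
        k = len(data.terms[t])
        term_map[t] = np.arange(pos, pos + k)
        pos += k
    if data.family == "linear":
        return _fit_linear(X, data.y, columns, term_map)
    if data.family == "logistic":
        return _fit_logistic(X, data.y, columns, term_map)
    return _fit_cox(X, data.y, data.event, columns, term_map)


def _fit_linear(X, y, columns, term_map) -> FittedModel:
    n, p = X.shape
    ym = y.mean()
    yc = y - ym
    if p:
        xm = X.mean(axis=0)
        Xc = X - xm
        G = Xc.T @ Xc
        Xy = Xc.T @ yc
        try:
            cf = linalg.cho_factor(G, lower=True)
        except linalg.LinAlgError as exc:
            raise SingularDesignError(
                "rank-deficient design (collinear columns)") from exc
        # a tiny pivot relative to the column scale means (near-)collinearity
        # that slipped through the factorization numerically
        if (np.diag(cf[0]) ** 2 <= 1e-10 * np.diag(G)).any():
            raise SingularDesignError(
                "rank-deficient design (collinear columns)")
        beta = linalg.cho_solve(cf, Xy)
        Ginv = linalg.cho_solve(cf, np.eye(p))
        rss = float(yc @ yc - beta @ Xy)
        if not np.isfinite(beta).all():
            raise SingularDesignError("numerically singular design")
    else:
        xm = np.zeros(0)
        beta = np.zeros(0)
        Ginv = np.zeros((0, 0))
        rss = float(yc @ yc)
    df_resid = n - p - 1
    if rss <= 0:
        raise FitError("zero residual variance (perfect fit)")
    sigma2 = rss / df_resid
    cov = sigma2 * Ginv
    bse = np.sqrt(np.diag(cov))
    loglik = -0.5 * n * (np.log(2.0 * np.pi * rss / n) + 1.0)
    intercept = float(ym - xm @ beta) if p else float(ym)
    int_var = sigma2 * (1.0 / n + (xm @ Ginv @ xm if p else 0.0))
    return FittedModel(
        family="linear", columns=columns, term_map=term_map, params=beta,
        bse=bse, cov=cov, loglik=loglik, aic=-2.0 * loglik + 2.0 * (p + 1),
        nobs=n, converged=True, intercept=intercept,
        intercept_se=float(np.sqrt(int_var)), df_resid=df_resid)


def _fit_logistic(X, y, columns, term_map) -> FittedModel:
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    n, p = X.shape
    exog = np.column_stack([np.ones(n), X]) if p else np.ones((n, 1))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, exog).fit(disp=0, maxiter=MAX_ITER,
                                        tol=LOGLIK_TOL)
    except PerfectSeparationError as exc:
        raise SeparationError(
            "perfect separation: diverging logistic coefficients") from exc
    except np.linalg.LinAlgError as exc:
        raise SingularDesignError(
            "rank-deficient design (collinear columns)") from exc
    params = np.asarray(res.params)
    if not np.isfinite(params).all() or np.abs(params[1:]).max(initial=0) > 50:
        raise SeparationError(
            "perfect separation: diverging logistic coefficients")
    cov_all = np.asarray(res.cov_params())
    loglik = float(res.llf)
    return FittedModel(
        family="logistic", columns=columns, term_map=term_map,
        params=params[1:], bse=np.sqrt(np.diag(cov_all))[1:],
        cov=cov_all[1:, 1:], loglik=loglik,
        aic=-2.0 * loglik + 2.0 * (p + 1), nobs=n,
        converged=bool(res.mle_retvals.get("converged", True)),
        intercept=float(params[0]),
        intercept_se=float(np.sqrt(cov_all[0, 0])))


def _fit_cox(X, time, event, columns, term_map) -> FittedModel:
    from statsmodels.duration.hazard_regression import PHReg

    n, p = X.shape
    if event.sum() < 1:
        raise FitError("no events in the data")
    if p == 0:
        # Null model: evaluate the Efron partial likelihood at beta = 0.
        mod = PHReg(time, np.zeros((n, 1)), status=event, ties="efron")
        ll0 = float(mod.loglike(np.zeros(1)))
        return FittedModel(family="cox", columns=(), term_map={},
                           params=np.zeros(0), bse=np.zeros(0),
                           cov=np.zeros((0, 0)), loglik=ll0,
                           aic=-2.0 * ll0, nobs=n, converged=True)
    mod = PHReg(time, X, status=event, ties="efron")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = mod.fit(maxiter=MAX_ITER, disp=False)
    except (np.linalg.LinAlgError, linalg.LinAlgError) as exc:
        raise SingularDesignError(
            "rank-deficient design (collinear columns)") from exc
    params = np.asarray(res.params)
    cov = np.asarray(res.cov_params())
    if not (np.isfinite(params).all() and np.isfinite(cov).all()):
        raise FitError("Cox partial-likelihood maximization failed")
    loglik = float(mod.loglike(params))
    return FittedModel(
        family="cox", columns=columns, term_map=term_map, params=params,
        bse=np.sqrt(np.diag(cov)), cov=cov, loglik=loglik,
        aic=-2.0 * loglik + 2.0 * p, nobs=n,
        converged=bool(np.isfinite(loglik)))


# ---------------------------------------------------------------------------
# Wald tests


def term_test(fit: FittedModel, term: str) -> float:
    """Two-sided Wald p-value for dropping ``term`` from ``fit``.

    Single-column terms use z = beta/se with a t reference (linear; residual
    df) or standard normal reference (logistic/Cox).  Multi-column terms use
    the quadratic-form Wald statistic with an F (linear) or chi-square
    reference on as many df as the term has columns.
    """
    if term not in fit.term_map:
        raise KeyError(f"term {term!r} is not in the fitted model")
    return float(term_pvalues(fit, (term,))[0])


def term_pvalues(fit: FittedModel, terms) -> np.ndarray:
    """Vectorized Wald p-values for several terms of one fit."""
    terms = tuple(terms)
    pvals = np.empty(len(terms))
    singles, s_pos = [], []
    for i, t in enumerate(terms):
        idx = fit.term_map[t]
        if len(idx) == 1:
            singles.append(int(idx[0]))
            s_pos.append(i)
        else:
            b = fit.params[idx]
            V = fit.cov[np.ix_(idx, idx)]
            try:
                W = float(b @ linalg.solve(V, b, assume_a="pos"))
            except linalg.LinAlgError as exc:
                raise SingularDesignError(
                    f"singular covariance block for term {t!r}") from exc
            q = len(idx)
            if fit.family == "linear":
                pvals[i] = stats.f.sf(W / q, q, fit.df_resid)
            else:
                pvals[i] = stats.chi2.sf(W, q)
    if singles:
        z = np.abs(fit.params[singles] / fit.bse[singles])
        if fit.family == "linear":
            pv = 2.0 * special.stdtr(fit.df_resid, -z)
        else:
            pv = 2.0 * special.ndtr(-z)
        pvals[s_pos] = pv
    return pvals
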