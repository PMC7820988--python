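"""Independent reference implementations used only by the test suite.

These deliberately avoid the package's own code paths: the naive backward
elimination oracle drives statsmodels OLS fits and statsmodels Wald tests,
and the Cox oracle maximizes a hand-written partial likelihood by grid
search.
"""

import numpy as np
import statsmodels.api as sm


def naive_backward_eliminate(data, alpha, forced=()):
    """Step-by-step backward elimination via statsmodels OLS.

    Returns ``(selected_terms, trace)`` with the same conventions as the
    package: remove the non-forced term with the largest p >= alpha, ties
    broken towards the later term, until none qualifies.
    """
    assert data.family == "linear"
    included = list(data.term_names)
    trace = []
    while True:
        cols = [c for t in included for c in data.term_columns(t)]
        idx = [data.columns.index(c) for c in cols]
        X = sm.add_constant(data.X[:, idx])
        res = sm.OLS(data.y, X).fit()
        worst, worst_p = None, -1.0
        for t in included:
            if t in forced:
                continue
            tcols = data.term_columns(t)
            if len(tcols) == 1:
                p = float(res.pvalues[1 + cols.index(tcols[0])])
            else:
                R = np.zeros((len(tcols), X.shape[1]))
                for r, c in enumerate(tcols):
                    R[r, 1 + cols.index(c)] = 1.0
                p = float(res.wald_test(R, use_f=True, scalar=True).pvalue)
            if p >= alpha and p >= worst_p:
                worst, worst_p = t, p
        if worst is None:
            break
        included.remove(worst)
        trace.append((worst, worst_p))
    return tuple(included), tuple(trace)


def cox_partial_loglik(beta, times, events, x):
    """Breslow==Efron partial log-likelihood for untied data, one covariate."""
    order = np.argsort(times)
    times, events, x = times[order], events[order], x[order]
    ll = 0.0
    eta = beta * x
    for i in range(len(times)):
        if events[i] == 1:
            risk = eta[i:]  # all with time >= t_i (no ties)
            ll += eta[i] - np.log(np.sum(np.exp(risk)))
    return ll


def cox_grid_argmax(times, events, x, lo=-3.0, hi=3.0, n=120001):
    grid = np.linspace(lo, hi, n)
    ll = np.array([cox_partial_loglik(b, times, events, x) for b in grid])
    return float(grid[np.argmax(ll)])


def chi2_sf_by_quadrature(w, df):
    """Upper-tail chi-square probability by numerical integration of the
    density, independent of scipy.stats.chi2."""
    from math import gamma
    from scipy.integrate import quad

    def dens(t):
        return t ** (df / 2.0 - 1.0) * np.exp(-t / 2.0) / (
            2.0 ** (df / 2.0) * gamma(df / 2.0))

    val, _ = quad(dens, w, np.inf)
    return val
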