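"""Backward elimination with a significance-level stopping rule.

``backward_eliminate`` starts from the global model and iteratively removes
the least significant non-forced term (largest Wald p-value >= alpha),
refitting after each removal, until every remaining non-forced term has
p < alpha.  The level ``alpha = 0.157`` (:data:`ALPHA_AIC`) makes 1-df
elimination approximately equivalent to stepwise AIC improvement, because
dropping a term with Wald statistic z changes the AIC by about z**2 - 2 and
P(chi2_1 > 2) = 0.157.

Any callable ``Dataset -> SelectionResult`` satisfies the selector plugin
contract used by the resampling and simulation engines; ``be_selector`` and
``full_model_selector`` are the built-in factories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import Dataset
from .exceptions import EliminationError, SelstabError
from .models import FittedModel, fit_model, term_pvalues

logger = logging.getLogger(__name__)

#: Significance level at which 1-df backward elimination is approximately
#: equivalent to AIC-based elimination: P(chi2_1 > 2) rounded to 3 decimals.
ALPHA_AIC = round(float(stats.chi2.sf(2.0, 1)), 3)


@dataclass
class SelectionResult:
    """Outcome of one selection run.

    ``coefficients`` (and ``standard_errors``) are padded over *all* dataset
    columns: a coefficient is exactly 0 iff its term was eliminated.
    ``trace`` lists ``(term, p_value)`` in elimination order.
    """

    selected_terms: tuple
    columns: tuple
    coefficients: np.ndarray
    standard_errors: np.ndarray
    model: FittedModel
    trace: tuple
    forced_terms: tuple = ()

    @property
    def eliminated_terms(self) -> tuple:
        return tuple(t for t, _ in self.trace)

    def coef(self, column: str) -> float:
        return float(self.coefficients[self.columns.index(column)])


def backward_eliminate(data: Dataset, alpha: float = ALPHA_AIC,
                       forced_terms=(), test: str = "wald"
                       ) -> SelectionResult:
    """Backward elimination at significance level ``alpha``.

    Parameters
    ----------
    alpha : float in (0, 1]
        Stopping level; ``alpha=1.0`` keeps every term, ``ALPHA_AIC``
        emulates AIC-based elimination.
    forced_terms : iterable of str
        Terms exempt from elimination (the intercept is implicitly forced).
    test : {"wald", "lr"}
        Term test used for elimination decisions.  ``"lr"`` refits without
        each candidate term and refers twice the log-likelihood drop to a
        chi-square distribution.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    if test not in ("wald", "lr"):
        raise ValueError("test must be 'wald' or 'lr'")
    forced = tuple(forced_terms)
    unknown = set(forced) - set(data.term_names)
    if unknown:
        raise KeyError(f"forced terms not in data: {sorted(unknown)}")
    order = {t: i for i, t in enumerate(data.term_names)}
    included = list(data.term_names)
    trace: list = []
    fit = _refit(data, included, trace)
    while True:
        cands = [t for t in included if t not in forced]
        if not cands:
            break
        if test == "wald":
            pv = term_pvalues(fit, cands)
        else:
            pv = _lr_pvalues(data, fit, included, cands, trace)
        # Pick the largest p >= alpha; ties go to the later term in the
        # dataset's term order.
        worst, worst_p = None, -1.0
        for t, p in zip(cands, pv):
            if p >= alpha and p >= worst_p:
                if p == worst_p:
                    logger.debug("tie at p=%.6g between %r and %r; "
                                 "dropping the later term", p, worst, t)
                worst, worst_p = t, p
        if worst is None:
            break
        included.remove(worst)
        trace.append((worst, float(worst_p)))
        fit = _refit(data, included, trace)
    return _build_result(data, included, fit, trace, forced)


def _refit(data, included, trace) -> FittedModel:
    try:
        return fit_model(data, included)
    except SelstabError as exc:
        raise EliminationError(f"refit failed after eliminating "
                               f"{[t for t, _ in trace]}: {exc}",
                               trace=trace) from exc


def _lr_pvalues(data, fit, included, cands, trace) -> np.ndarray:
    pv = np.empty(len(cands))
    for i, t in enumerate(cands):
        reduced = _refit(data, [u for u in included if u != t], trace)
        lr = max(0.0, 2.0 * (fit.loglik - reduced.loglik))
        pv[i] = stats.chi2.sf(lr, len(data.terms[t]))
    return pv


def _build_result(data, included, fit, trace, forced) -> SelectionResult:
    coef = np.zeros(data.p)
    se = np.zeros(data.p)
    col_index = {c: j for j, c in enumerate(data.columns)}
    for c, b, s in zip(fit.columns, fit.params, fit.bse):
        coef[col_index[c]] = b
        se[col_index[c]] = s
    return SelectionResult(
        selected_terms=tuple(included), columns=data.columns,
        coefficients=coef, standard_errors=se, model=fit,
        trace=tuple(trace), forced_terms=tuple(forced))


def be_selector(alpha: float = ALPHA_AIC, forced_terms=(),
                test: str = "wald"):
    """Factory: a selector applying ``backward_eliminate`` with fixed options."""
    def select(data: Dataset) -> SelectionResult:
        return backward_eliminate(data, alpha=alpha,
                                  forced_terms=forced_terms, test=test)
    select.__name__ = f"be(alpha={alpha})"
    return select


def full_model_selector():
    """Selector that always returns the global model (no elimination)."""
    def select(data: Dataset) -> SelectionResult:
        fit = fit_model(data)
        return _build_result(data, list(data.term_names), fit, [], ())
    select.__name__ = "full_model"
    return select
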