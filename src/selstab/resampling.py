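"""Bootstrap and subsampling engines.

``draw_indices`` produces reproducible resample index sets: bootstrap
resamples of size N drawn with replacement, or subsamples of size
``m = floor(proportion * N)`` drawn without replacement (common choices
0.5, 0.632 -- the limiting probability that an observation appears in a
bootstrap resample -- and 0.8).  Per-resample random substreams are spawned
deterministically from one seed, so extending B re-uses the earlier draws.

``resample_and_select`` applies a selector to every resampled dataset and
collects the zero-padded coefficient estimates into a
:class:`SelectionEnsemble`, the input to every stability measure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .data import Dataset
from .exceptions import FitError, EliminationError, ResamplingError
from .selection import SelectionResult

SCHEMES = ("bootstrap", "subsample")


@dataclass(frozen=True)
class ResamplePlan:
    """How to draw B resamples: scheme, size, and seed."""

    scheme: str
    B: int = 1000
    proportion: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.scheme == "subsample":
            if self.proportion is None or not 0.0 < self.proportion < 1.0:
                raise ValueError("subsampling needs 0 < proportion < 1")
        elif self.proportion is not None:
            raise ValueError("proportion is only valid for subsampling")

    def resample_size(self, N: int) -> int:
        """Resample size: N (bootstrap) or floor(proportion*N) (subsample)."""
        if self.scheme == "bootstrap":
            return N
        m = math.floor(self.proportion * N)
        if not 0 < m < N:
            raise ValueError(f"subsample size m={m} must satisfy 0 < m < N")
        return m

    def with_seed(self, seed: int) -> "ResamplePlan":
        return replace(self, seed=seed)


def subsample_plan(proportion: float, B: int = 1000, seed: int = 0
                   ) -> ResamplePlan:
    """Shorthand for the S_p subsampling plans (p = 0.5, 0.632, 0.8, ...)."""
    return ResamplePlan("subsample", B=B, proportion=proportion, seed=seed)


def bootstrap_plan(B: int = 1000, seed: int = 0) -> ResamplePlan:
    return ResamplePlan("bootstrap", B=B, seed=seed)


def draw_indices(N: int, plan: ResamplePlan) -> np.ndarray:
    """Draw the B resample index sets as a ``(B, m)`` integer array."""
    if N < 2:
        raise ValueError("N must be >= 2")
    m = plan.resample_size(N)
    children = np.random.SeedSequence(plan.seed).spawn(plan.B)
    out = np.empty((plan.B, m), dtype=np.intp)
    for b, child in enumerate(children):
        rng = np.random.default_rng(child)
        if plan.scheme == "bootstrap":
            out[b] = rng.integers(0, N, size=N)
        else:
            out[b] = rng.permutation(N)[:m]
    return out


@dataclass
class SelectionEnsemble:
    """Per-resample selection results, stacked.

    ``coefficients``: (B_ok, p) zero-padded coefficient estimates, one row
    per *successful* resample; ``selected``: (B_ok, n_terms) boolean
    selection indicators.  Resamples on which the selector failed (singular
    design, separation, non-convergence, ...) are excluded from all
    measures; their count is kept in ``n_failed``.
    """

    plan: ResamplePlan
    term_names: tuple
    columns: tuple
    coefficients: np.ndarray
    selected: np.ndarray
    n_failed: int
    data: Dataset | None = None

    @property
    def n_resamples(self) -> int:
        """Number of successful resamples (the denominator of all measures)."""
        return self.coefficients.shape[0]

    def term_index(self, term: str) -> int:
        return self.term_names.index(term)

    def column_index(self, column: str) -> int:
        return self.columns.index(column)

    def selected_sets(self) -> list:
        """Selected term set of each successful resample, as tuples."""
        names = np.asarray(self.term_names, dtype=object)
        return [tuple(names[row]) for row in self.selected]


def resample_and_select(data: Dataset, plan: ResamplePlan, selector
                        ) -> SelectionEnsemble:
    """Run ``selector`` on every resample of ``data`` under ``plan``.

    Aborts with :class:`ResamplingError` if more than half of the resamples
    fail, since measures over the remainder would be badly distorted.
    """
    indices = draw_indices(data.n, plan)
    term_names = data.term_names
    term_of_col = np.empty(data.p, dtype=np.intp)
    for ti, t in enumerate(term_names):
        term_of_col[data.terms[t]] = ti
    coefs, sel_rows = [], []
    n_failed = 0
    for idx in indices:
        sub = data.subset(idx)
        try:
            res: SelectionResult = selector(sub)
        except (FitError, EliminationError):
            n_failed += 1
            continue
        if res.model is not None and not res.model.converged:
            n_failed += 1
            continue
        coefs.append(res.coefficients)
        row = np.zeros(len(term_names), dtype=bool)
        row[[term_names.index(t) for t in res.selected_terms]] = True
        sel_rows.append(row)
    if n_failed > plan.B / 2:
        raise ResamplingError(
            f"{n_failed}/{plan.B} resamples failed "
            f"({plan.scheme}, m={plan.resample_size(data.n)}); "
            "the model is too unstable to resample at this size")
    return SelectionEnsemble(
        plan=plan, term_names=term_names, columns=data.columns,
        coefficients=np.asarray(coefs), selected=np.asarray(sel_rows),
        n_failed=n_failed, data=data)
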