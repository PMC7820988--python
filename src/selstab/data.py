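"""Rectangular datasets with named covariate terms.

A :class:`Dataset` couples an outcome (continuous, binary, or time+event),
an ``N x p`` covariate matrix, and an ordered partition of the columns into
named *terms*.  A term is the unit of selection: either a single column or a
group of columns (e.g. the dummy columns of a categorical factor) that enter
and leave a model together.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError

FAMILIES = ("linear", "logistic", "cox")


class Dataset:
    """Outcome, covariates and term structure for one model family.

    Parameters
    ----------
    X : ndarray of shape (N, p)
        Covariate matrix (float).
    y : ndarray of shape (N,)
        Outcome: continuous values (``linear``), 0/1 (``logistic``), or
        follow-up times >= 0 (``cox``, together with ``event``).
    terms : mapping of str to sequence of int
        Ordered map from term name to the column indices it owns.  Terms must
        be disjoint and cover all columns.  The order defines the tie-break
        order used by backward elimination.
    family : {"linear", "logistic", "cox"}
    columns : sequence of str, optional
        Column names; defaults to ``x1..xp``.
    event : ndarray of shape (N,), optional
        0/1 event indicator, required for (and exclusive to) ``family="cox"``.
    """

    __slots__ = ("X", "y", "event", "terms", "family", "columns")

    def __init__(self, X, y, terms, family, columns=None, event=None,
                 validate=True):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.event = None if event is None else np.asarray(event, dtype=float)
        if columns is None:
            columns = tuple(f"x{i + 1}" for i in range(self.X.shape[1]))
        self.columns = tuple(columns)
        self.terms = {str(k): np.asarray(v, dtype=np.intp)
                      for k, v in terms.items()}
        self.family = family
        if validate:
            self._validate()

    def _validate(self):
        if self.family not in FAMILIES:
            raise ConfigError(f"unknown family {self.family!r}; "
                              f"expected one of {FAMILIES}")
        if self.X.ndim != 2:
            raise ConfigError("covariate matrix must be 2-dimensional")
        n, p = self.X.shape
        if len(self.columns) != p:
            raise ConfigError("number of column names does not match X")
        if self.y.shape != (n,):
            raise ConfigError("outcome length does not match X")
        if not np.isfinite(self.X).all() or not np.isfinite(self.y).all():
            raise ConfigError("missing or non-finite values in the data; "
                              "imputation is not performed")
        covered = np.concatenate([v for v in self.terms.values()]) \
            if self.terms else np.empty(0, dtype=np.intp)
        if len(covered) != p or len(np.unique(covered)) != p or (
                len(covered) and (covered.min() < 0 or covered.max() >= p)):
            raise ConfigError("terms must partition the covariate columns "
                              "(disjoint and covering)")
        if self.family == "cox":
            if self.event is None:
                raise ConfigError("family='cox' requires an event indicator")
            if not np.isin(self.event, (0.0, 1.0)).all():
                raise ConfigError("event indicator must be 0/1")
            if (self.y < 0).any():
                raise ConfigError("follow-up times must be >= 0")
        else:
            if self.event is not None:
                raise ConfigError("event indicator is only valid with "
                                  "family='cox'")
            if self.family == "logistic" and \
                    not np.isin(self.y, (0.0, 1.0)).all():
                raise ConfigError("logistic outcome must be 0/1")

    # -- basic properties --------------------------------------------------

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def term_names(self) -> tuple:
        return tuple(self.terms)

    def term_columns(self, term: str) -> tuple:
        """Names of the columns belonging to ``term``."""
        return tuple(self.columns[i] for i in self.terms[term])

    def column_term(self, column: str) -> str:
        """Name of the term owning ``column``."""
        j = self.columns.index(column)
        for t, idx in self.terms.items():
            if j in idx:
                return t
        raise KeyError(column)

    # -- derived datasets --------------------------------------------------

    def subset(self, rows) -> "Dataset":
        """Row subset (used by the resampling engine); shares term metadata."""
        return Dataset(self.X[rows], self.y[rows], self.terms, self.family,
                       columns=self.columns,
                       event=None if self.event is None else self.event[rows],
                       validate=False)

    def with_X(self, X) -> "Dataset":
        return Dataset(X, self.y, self.terms, self.family,
                       columns=self.columns, event=self.event, validate=False)

    # -- construction helpers ----------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, *, family: str,
                       outcome: str | None = None,
                       time: str | None = None, event: str | None = None,
                       terms: Mapping[str, Sequence[str]] | None = None,
                       covariates: Sequence[str] | None = None) -> "Dataset":
        """Build a dataset from a data frame.

        ``terms`` maps term names to column-name groups; unnamed covariate
        columns each become their own single-column term, in frame order.
        """
        if df.isna().any().any():
            raise ConfigError("missing values in input data; rows with "
                              "missing values must be removed beforehand")
        if family == "cox":
            if time is None or event is None:
                raise ConfigError("family='cox' needs time= and event= "
                                  "column names")
            reserved = {time, event}
            y = df[time].to_numpy(dtype=float)
            ev = df[event].to_numpy(dtype=float)
        else:
            if outcome is None:
                raise ConfigError("outcome= column name is required")
            reserved = {outcome}
            y = df[outcome].to_numpy(dtype=float)
            ev = None
        missing = reserved - set(df.columns)
        if missing:
            raise ConfigError(f"columns not in data: {sorted(missing)}")
        if covariates is None:
            covariates = [c for c in df.columns if c not in reserved]
        covariates = list(covariates)
        terms = {} if terms is None else {k: list(v) for k, v in terms.items()}
        named = [c for cols in terms.values() for c in cols]
        bad = set(named) - set(covariates)
        if bad:
            raise ConfigError(f"term columns not among covariates: "
                              f"{sorted(bad)}")
        if len(named) != len(set(named)):
            raise ConfigError("a column may belong to at most one term")
        for c in covariates:
            if c not in named:
                terms[c] = [c]
        col_index = {c: i for i, c in enumerate(covariates)}
        term_idx = {t: [col_index[c] for c in cols]
                    for t, cols in terms.items()}
        try:
            Xmat = df[covariates].to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"non-numeric covariate column: {exc}") from exc
        return cls(Xmat, y, term_idx, family, columns=covariates, event=ev)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.columns))
        if self.family == "cox":
            df.insert(0, "event", self.event)
            df.insert(0, "time", self.y)
        else:
            df.insert(0, "y", self.y)
        return df


def read_dataset(path, *, family: str, outcome: str | None = None,
                 time: str | None = None, event: str | None = None,
                 terms=None, covariates=None) -> Dataset:
    """Read a CSV file (header row required) into a :class:`Dataset`."""
    df = pd.read_csv(path)
    return Dataset.from_dataframe(df, family=family, outcome=outcome,
                                  time=time, event=event, terms=terms,
                                  covariates=covariates)
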