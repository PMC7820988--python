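"""Resampling-based model stability measures and the stability report.

Given a :class:`~selstab.resampling.SelectionEnsemble` of B selection runs
and the global-model fit on the original data, this module computes

* **VIF** (variable inclusion frequency): fraction of resamples selecting a
  term, ``sum_b I(beta_j^b != 0) / B``;
* **MSF** (model selection frequency): fraction of resamples selecting an
  exact term set;
* **RCB** (relative conditional bias): ``sum_b beta_j^b / (beta~_j *
  VIF_j * B) - 1``, the relative bias of a selected coefficient against the
  global-model estimate, conditional on selection (>0: overestimation);
* **RMSDR** (root mean squared difference ratio):
  ``sqrt(sum_b (beta_j^b - beta~_j)^2 / B) / se~_j``, the selection-induced
  RMSE inflation relative to the global-model SE (>1: inflation);
* **SF** (shrinkage factor): ``(1 + RCB)^-1`` with a delta-method SE, a
  multiplicative correction for selection-induced overestimation;
* the pairwise inclusion frequency matrix (how often two terms are selected
  together; its diagonal is the VIF).

``stability_report`` assembles everything into one table, by default using
subsampling with m = 0.5N for the frequency measures and the bootstrap for
RCB/RMSDR — the schemes that estimate each group most reliably.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import Dataset
from .exceptions import SelstabError
from .models import FittedModel, fit_model, term_pvalues
from .resampling import (ResamplePlan, SelectionEnsemble, bootstrap_plan,
                         resample_and_select, subsample_plan)
from .selection import ALPHA_AIC, SelectionResult, be_selector

#: Interpret RCB with caution for terms selected in fewer than this fraction
#: of resamples: for (near-)nonpredictors the RCB estimand is not defined,
#: although an estimate is still produced.
RCB_CAVEAT_VIF = 0.5


# ---------------------------------------------------------------------------
# term-level measures


def vif(ens: SelectionEnsemble, term: str) -> float:
    """Variable inclusion frequency of ``term`` (multi-column terms count
    once)."""
    return float(ens.selected[:, ens.term_index(term)].mean())


def vif_all(ens: SelectionEnsemble) -> pd.Series:
    """VIF of every term, in term order."""
    return pd.Series(ens.selected.mean(axis=0), index=list(ens.term_names),
                     name="vif")


def msf(ens: SelectionEnsemble, model) -> float:
    """Model selection frequency: fraction of resamples selecting exactly
    the term set ``model``."""
    model = set(model)
    unknown = model - set(ens.term_names)
    if unknown:
        raise KeyError(f"terms not in ensemble: {sorted(unknown)}")
    mask = np.array([t in model for t in ens.term_names])
    return float((ens.selected == mask).all(axis=1).mean())


def top_models(ens: SelectionEnsemble, k: int | None = None) -> pd.DataFrame:
    """Distinct selected models ranked by frequency (ties: first occurrence).

    Frequencies over all distinct models sum to 1 by construction.
    """
    counts: dict = {}
    first: dict = {}
    for i, s in enumerate(ens.selected_sets()):
        counts[s] = counts.get(s, 0) + 1
        first.setdefault(s, i)
    ranked = sorted(counts, key=lambda s: (-counts[s], first[s]))
    if k is not None:
        ranked = ranked[:k]
    B = ens.n_resamples
    return pd.DataFrame({
        "model": [" + ".join(s) if s else "(empty)" for s in ranked],
        "n_terms": [len(s) for s in ranked],
        "frequency": [counts[s] / B for s in ranked],
    })


@dataclass
class RCBEstimate:
    """RCB point estimate with the SE of the mean conditional ratio."""

    value: float
    se: float
    n_selected: int
    vif: float
    caveat: bool = False
    note: str | None = None

    def __float__(self) -> float:
        return self.value


def _col_info(ens, global_fit, name):
    """Resolve a column name shared by the ensemble and the global fit.

    RCB and RMSDR are per-column quantities: a multi-column term must be
    queried one column at a time.
    """
    if name not in ens.columns:
        if name in ens.term_names and ens.data is not None:
            cols = ens.data.term_columns(name)
            if len(cols) == 1:
                name = cols[0]
            else:
                raise SelstabError(
                    f"term {name!r} has several columns; RCB/RMSDR are "
                    f"computed per column — pass one of its column names")
        else:
            raise KeyError(
                f"{name!r} is not a covariate column of the ensemble")
    j = ens.column_index(name)
    jg = global_fit.columns.index(name)
    # which term owns this column?
    ti = None
    for t in ens.term_names:
        if ens.data is not None and name in ens.data.term_columns(t):
            ti = ens.term_index(t)
            break
    if ti is None:  # fall back: single-column terms share the column name
        ti = ens.term_index(name) if name in ens.term_names else None
    if ti is None:
        raise KeyError(f"cannot map column {name!r} to a term")
    return j, jg, ti


def rcb(ens: SelectionEnsemble, global_fit: FittedModel, column: str
        ) -> RCBEstimate:
    """Relative conditional bias of one coefficient.

    Computed both as ``sum_b beta^b / (beta~ * VIF * B) - 1`` and as the
    mean of ``beta^b / beta~`` over the resamples that selected the term,
    minus 1; the two forms are algebraically identical and asserted to agree
    to 1e-12.  Undefined (NaN, with a note) when the term was never
    selected.
    """
    j, jg, ti = _col_info(ens, global_fit, column)
    b = ens.coefficients[:, j]
    sel = ens.selected[:, ti]
    B = ens.n_resamples
    v = float(sel.mean())
    tilde = float(global_fit.params[jg])
    if v == 0.0:
        return RCBEstimate(value=float("nan"), se=float("nan"), n_selected=0,
                           vif=0.0, caveat=True,
                           note="never selected: RCB can only be estimated "
                                "if the covariate is selected at least once")
    direct = float(b.sum() / (tilde * v * B) - 1.0)
    ratios = b[sel] / tilde
    conditional = float(ratios.mean() - 1.0)
    if abs(direct - conditional) > 1e-12 * max(1.0, abs(direct)):
        raise AssertionError(
            f"RCB dual-formula mismatch for {column!r}: "
            f"{direct!r} vs {conditional!r}")
    n_sel = int(sel.sum())
    se = float(ratios.std(ddof=1) / np.sqrt(n_sel)) if n_sel > 1 \
        else float("nan")
    return RCBEstimate(value=conditional, se=se, n_selected=n_sel, vif=v,
                       caveat=v < RCB_CAVEAT_VIF)


def rmsdr(ens: SelectionEnsemble, global_fit: FittedModel, column: str
          ) -> float:
    """Root mean squared difference ratio of one coefficient.

    The numerator averages squared deviations from the global estimate over
    *all* resamples, counting non-selection as a deviation of ``beta~``
    itself (the padded estimate is 0); the denominator is the model-based SE
    from the global model.
    """
    j, jg, _ = _col_info(ens, global_fit, column)
    b = ens.coefficients[:, j]
    tilde = float(global_fit.params[jg])
    sigma = float(global_fit.bse[jg])
    if sigma <= 0:
        raise SelstabError(f"non-positive global SE for {column!r}")
    return float(np.sqrt(np.mean((b - tilde) ** 2)) / sigma)


def shrinkage_factor(rcb_value, se_rcb: float | None = None):
    """Shrinkage factor SF = (1 + RCB)^-1 with its delta-method SE.

    Accepts a plain RCB value or an :class:`RCBEstimate` (whose ``se`` is
    then used).  Returns ``(sf, se_sf)``; ``se_sf`` is None when no RCB SE
    is available.  Undefined for RCB <= -1.
    """
    if isinstance(rcb_value, RCBEstimate):
        if se_rcb is None:
            se_rcb = rcb_value.se
        rcb_value = rcb_value.value
    rcb_value = float(rcb_value)
    if np.isnan(rcb_value):
        return float("nan"), float("nan")
    if rcb_value <= -1.0:
        raise ValueError("shrinkage factor undefined for RCB <= -1")
    sf = 1.0 / (1.0 + rcb_value)
    se_sf = None if se_rcb is None else float(se_rcb) * sf ** 2
    return sf, se_sf


def pairwise_inclusion(ens: SelectionEnsemble) -> pd.DataFrame:
    """Term-by-term matrix of joint inclusion frequencies (diagonal = VIF)."""
    S = ens.selected.astype(float)
    M = (S.T @ S) / ens.n_resamples
    names = list(ens.term_names)
    return pd.DataFrame(M, index=names, columns=names)


# ---------------------------------------------------------------------------
# vectorized helpers used by the simulation engine


def rcb_all(ens: SelectionEnsemble, global_fit: FittedModel,
            tilde: np.ndarray | None = None) -> np.ndarray:
    """RCB for every column at once (NaN where the owning term's VIF is 0).

    ``tilde`` may supply reference coefficients (e.g. true values when
    approximating estimands) aligned with ``ens.columns``; the default is
    the global-model estimate.
    """
    if tilde is None:
        order = [global_fit.columns.index(c) for c in ens.columns]
        tilde = np.asarray(global_fit.params)[order]
    vifc = _column_vif(ens)
    mean_b = ens.coefficients.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = mean_b / (tilde * vifc) - 1.0
    out[vifc == 0] = np.nan
    return out


def rmsdr_all(ens: SelectionEnsemble, global_fit: FittedModel) -> np.ndarray:
    order = [global_fit.columns.index(c) for c in ens.columns]
    tilde = np.asarray(global_fit.params)[order]
    sigma = np.asarray(global_fit.bse)[order]
    dev2 = (ens.coefficients - tilde) ** 2
    return np.sqrt(dev2.mean(axis=0)) / sigma


def _column_vif(ens: SelectionEnsemble) -> np.ndarray:
    """Term-level VIF expanded to the columns each term owns."""
    v = ens.selected.mean(axis=0)
    out = np.empty(len(ens.columns))
    data = ens.data
    if data is not None:
        for ti, t in enumerate(ens.term_names):
            out[list(data.terms[t])] = v[ti]
    else:  # ensembles built by hand in tests: single-column terms in order
        out[:] = v
    return out


# ---------------------------------------------------------------------------
# the report


@dataclass
class StabilityReport:
    """Stability assessment of one selection run on one dataset.

    ``table`` has one row per covariate column, sorted by VIF (descending):
    global estimate/SE, VIF, selected-model estimate/SE (blank when not
    selected), RMSDR, RCB (x100), SF and its SE.  ``model_frequencies``
    ranks the distinct models of the inclusion ensemble; ``pairwise`` is the
    joint inclusion matrix.
    """

    table: pd.DataFrame
    model_frequencies: pd.DataFrame
    pairwise: pd.DataFrame
    selected_terms: tuple
    msf_selected: float
    meta: dict = field(default_factory=dict)

    _CSV_COLUMNS = ("term", "estimate_global", "se_global", "vif_pct",
                    "estimate_selected", "se_selected", "rmsdr", "rcb_x100",
                    "sf", "se_sf", "rcb_caveat")

    def validate(self) -> None:
        """Assert the structural invariants of the report."""
        freq = self.model_frequencies["frequency"]
        if abs(float(freq.sum()) - 1.0) > 1e-9:
            raise AssertionError("model frequencies must sum to 1")
        v = self.table.set_index("term")["vif_pct"] / 100.0
        vifs = v.groupby(level=0).first()
        for _, row in self.model_frequencies.iterrows():
            terms = () if row["model"] == "(empty)" \
                else tuple(row["model"].split(" + "))
            f = row["frequency"]
            for t in vifs.index:
                bound = vifs[t] if t in terms else 1.0 - vifs[t]
                if f > bound + 1e-9:
                    raise AssertionError(
                        f"MSF {f} exceeds bound {bound} from term {t!r}")
        if not (self.table["vif_pct"].is_monotonic_decreasing):
            raise AssertionError("report rows must be sorted by VIF")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="column",
                          columns=list(self._CSV_COLUMNS),
                          float_format="%.6g")

    def to_json(self, path=None):
        payload = {
            "meta": self.meta,
            "selected_terms": list(self.selected_terms),
            "msf_selected": self.msf_selected,
            "table": json.loads(
                self.table.reset_index().to_json(orient="records")),
            "model_frequencies": json.loads(
                self.model_frequencies.to_json(orient="records")),
            "pairwise": json.loads(self.pairwise.to_json(orient="split")),
        }
        if path is None:
            return json.dumps(payload, indent=1, sort_keys=True)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
        return None

    def __str__(self) -> str:
        with pd.option_context("display.width", 120,
                               "display.float_format", "{:.3f}".format):
            head = (f"Stability report ({self.meta.get('family', '?')}, "
                    f"N={self.meta.get('N', '?')}): selected model = "
                    f"{' + '.join(self.selected_terms) or '(empty)'} "
                    f"[MSF {100 * self.msf_selected:.1f}%]")
            return f"{head}\n{self.table[list(self._CSV_COLUMNS)]}"


DEFAULT_INCLUSION_PLAN = subsample_plan(0.5, B=1000, seed=101)
DEFAULT_BIAS_PLAN = bootstrap_plan(B=1000, seed=202)


def stability_report(data: Dataset, *, alpha: float = ALPHA_AIC,
                     forced_terms=(), selector=None,
                     inclusion_plan: ResamplePlan | None = None,
                     bias_plan: ResamplePlan | None = None
                     ) -> StabilityReport:
    """Fit, select, resample twice, and assemble the stability report.

    VIF/MSF and the pairwise matrix come from ``inclusion_plan`` (default
    subsampling, m = 0.5N, B = 1000); RCB/RMSDR/SF from ``bias_plan``
    (default bootstrap, B = 1000), reflecting which scheme estimates each
    measure reliably.
    """
    selector = selector or be_selector(alpha=alpha, forced_terms=forced_terms)
    inclusion_plan = inclusion_plan or DEFAULT_INCLUSION_PLAN
    bias_plan = bias_plan or DEFAULT_BIAS_PLAN
    global_fit = fit_model(data)
    sel: SelectionResult = selector(data)
    ens_inc = resample_and_select(data, inclusion_plan, selector)
    ens_bias = resample_and_select(data, bias_plan, selector)

    vifs = vif_all(ens_inc)
    rows = []
    for term in data.term_names:
        for col in data.term_columns(term):
            jg = global_fit.columns.index(col)
            r = rcb(ens_bias, global_fit, col)
            try:
                sf, se_sf = shrinkage_factor(r)
            except ValueError:   # RCB <= -1: SF undefined for this term
                sf, se_sf = float("nan"), float("nan")
            selected = term in sel.selected_terms
            rows.append({
                "column": col,
                "term": term,
                "estimate_global": float(global_fit.params[jg]),
                "se_global": float(global_fit.bse[jg]),
                "vif_pct": 100.0 * float(vifs[term]),
                "estimate_selected": sel.coef(col) if selected
                else float("nan"),
                "se_selected":
                    float(sel.standard_errors[data.columns.index(col)])
                    if selected else float("nan"),
                "rmsdr": rmsdr(ens_bias, global_fit, col),
                "rcb_x100": 100.0 * r.value,
                "sf": sf,
                "se_sf": float("nan") if se_sf is None else se_sf,
                "rcb_caveat": r.caveat,
            })
    table = pd.DataFrame(rows).set_index("column")
    table = table.sort_values("vif_pct", ascending=False, kind="stable")

    report = StabilityReport(
        table=table,
        model_frequencies=top_models(ens_inc),
        pairwise=pairwise_inclusion(ens_inc),
        selected_terms=sel.selected_terms,
        msf_selected=msf(ens_inc, sel.selected_terms),
        meta={
            "family": data.family,
            "N": data.n,
            "alpha": alpha,
            "selector": getattr(selector, "__name__", repr(selector)),
            "inclusion_plan": {"scheme": inclusion_plan.scheme,
                               "B": inclusion_plan.B,
                               "proportion": inclusion_plan.proportion,
                               "seed": inclusion_plan.seed,
                               "n_failed": ens_inc.n_failed},
            "bias_plan": {"scheme": bias_plan.scheme, "B": bias_plan.B,
                          "proportion": bias_plan.proportion,
                          "seed": bias_plan.seed,
                          "n_failed": ens_bias.n_failed},
        })
    report.validate()
    return report
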