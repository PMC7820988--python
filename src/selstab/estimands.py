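"""Simulation approximation of stability estimands and estimator evaluation.

The stability measures have well-defined estimands once a data-generating
mechanism and a selection procedure are fixed: the VIF estimand is the
probability that a covariate is selected in a fresh sample of size N, the
MSF estimand the probability that an exact covariate set is selected, and
RCB/RMSDR are defined against the *true* coefficients.
``approximate_estimands`` approximates them by simulating Q independent
datasets and applying the selector once per dataset.

``evaluate_estimators`` then measures how well the resampling-based
estimators (bootstrap and subsampling, computed within each simulated
dataset) recover those estimands, summarizing with mean and RMSE for the
frequency measures (VIF, MSF) and median bias / median absolute bias for
RCB and RMSDR, each with Monte-Carlo standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import Dataset
from .exceptions import FitError, EliminationError, ResamplingError
from .models import fit_model
from .resampling import ResamplePlan, resample_and_select
from .selection import be_selector
from .stability import rcb_all, rmsdr_all, _column_vif
from . import dgm


@dataclass
class EstimandTable:
    """Simulation-approximated estimands for one (DGM, N, selector) triple.

    ``per_term`` has one row per design column: the VIF estimand, the RCB
    estimand (predictors only; undefined for nonpredictors), the RMSDR
    estimand, and Monte-Carlo SEs.  ``msf`` is the selection probability of
    ``model`` (by default the true model).
    """

    per_term: pd.DataFrame
    msf: float
    msf_mcse: float
    model: tuple
    N: int
    Q: int
    n_failed: int = 0

    def vif(self, column: str) -> float:
        return float(self.per_term.loc[column, "vif"])


def approximate_estimands(cov_cfg, out_cfg, N: int, Q: int, *,
                          selector=None, model=None, seed: int = 0,
                          n_jobs: int = 1) -> EstimandTable:
    """Approximate the estimands over Q simulated datasets of size N.

    RCB uses the true coefficients in its denominator; the RMSDR
    denominator averages squared deviations of the per-dataset global-model
    estimates from the truth.  Datasets on which the selector fails are
    dropped and counted.
    """
    if Q < 2:
        raise ValueError("Q must be >= 2")
    selector = selector or be_selector()
    columns = cov_cfg.design_columns
    beta = out_cfg.beta_vector(columns)
    if model is None:
        model = out_cfg.predictor_columns(columns)
    model = tuple(model)

    children = np.random.SeedSequence(seed).spawn(Q)

    def one(child):
        data = dgm.generate_dataset(cov_cfg, out_cfg, N,
                                    np.random.default_rng(child))
        try:
            res = selector(data)
            gfit = fit_model(data)
        except (FitError, EliminationError):
            return None
        sel = np.array([t in res.selected_terms for t in data.term_names])
        return res.coefficients, sel, _pad_global(gfit, data)

    rows = _map(one, children, n_jobs)
    n_failed = sum(r is None for r in rows)
    rows = [r for r in rows if r is not None]
    if len(rows) < 2:
        raise ResamplingError("selector failed on almost every simulated "
                              "dataset")
    coefs = np.array([r[0] for r in rows])          # (Q_ok, p)
    selected = np.array([r[1] for r in rows])       # (Q_ok, n_terms)
    gcoefs = np.array([r[2] for r in rows])         # (Q_ok, p)
    Q_ok = len(rows)

    # per-column VIF (terms may own several columns)
    data0 = dgm.generate_dataset(cov_cfg, out_cfg, max(len(columns) + 3, 8),
                                 0)
    term_names = data0.term_names
    col_vif = np.empty(len(columns))
    vterm = selected.mean(axis=0)
    for ti, t in enumerate(term_names):
        col_vif[list(data0.terms[t])] = vterm[ti]

    is_pred = beta != 0.0
    mean_b = coefs.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rcb = mean_b / (beta * col_vif) - 1.0
        num = np.sqrt(((coefs - beta) ** 2).mean(axis=0))
        den = np.sqrt(((gcoefs - beta) ** 2).mean(axis=0))
        rmsdr = num / den
    rcb[~is_pred | (col_vif == 0)] = np.nan

    # Monte-Carlo SEs
    vif_mcse = np.sqrt(col_vif * (1.0 - col_vif) / Q_ok)
    rcb_mcse = np.full(len(columns), np.nan)
    for j in np.flatnonzero(is_pred & (col_vif > 0)):
        ti = [ti for ti, t in enumerate(term_names)
              if j in data0.terms[t]][0]
        sel_j = selected[:, ti]
        if sel_j.sum() > 1:
            ratios = coefs[sel_j, j] / beta[j]
            rcb_mcse[j] = ratios.std(ddof=1) / np.sqrt(sel_j.sum())
    rmsdr_mcse = _ratio_of_rms_mcse(coefs - beta, gcoefs - beta, rmsdr)

    mask = np.array([t in set(model) for t in term_names])
    hit = (selected == mask).all(axis=1)
    msf = float(hit.mean())
    per_term = pd.DataFrame({
        "term": _owner_terms(data0, columns),
        "true_beta": beta,
        "predictor": is_pred,
        "vif": col_vif,
        "vif_mcse": vif_mcse,
        "rcb": rcb,
        "rcb_mcse": rcb_mcse,
        "rmsdr": rmsdr,
        "rmsdr_mcse": rmsdr_mcse,
    }, index=list(columns))
    return EstimandTable(
        per_term=per_term, msf=msf,
        msf_mcse=float(np.sqrt(msf * (1.0 - msf) / Q_ok)),
        model=model, N=N, Q=Q_ok, n_failed=n_failed)


@dataclass
class PerformanceTable:
    """Performance of the resampling estimators against the estimands.

    ``table`` is tidy: one row per (measure, scheme, item) with the
    estimand, the mean estimate, RMSE (headline for VIF/MSF), median bias
    and median absolute bias (headline for RCB/RMSDR), plus Monte-Carlo
    SEs and failure counts.
    """

    table: pd.DataFrame
    estimands: EstimandTable
    N: int
    Q: int
    plans: dict = field(default_factory=dict)

    def row(self, measure: str, scheme: str, item: str) -> pd.Series:
        t = self.table
        sel = t[(t["measure"] == measure) & (t["scheme"] == scheme)
                & (t["item"] == item)]
        return sel.iloc[0]

    def mean_msf(self, scheme: str) -> float:
        return float(self.row("msf", scheme, "model")["mean"])


def evaluate_estimators(cov_cfg, out_cfg, N: int, Q: int, plans: dict, *,
                        selector=None, estimands: EstimandTable | None = None,
                        model=None, seed: int = 0, n_jobs: int = 1
                        ) -> PerformanceTable:
    """Estimate all four measures by resampling within each of Q simulated
    datasets, under each plan, and summarize against the estimands.

    ``plans`` maps scheme labels (e.g. ``"S_0.5"``, ``"bootstrap"``) to
    :class:`ResamplePlan` templates; each dataset re-seeds its plans from a
    deterministic substream so results do not depend on execution order.
    """
    selector = selector or be_selector()
    if estimands is None:
        estimands = approximate_estimands(cov_cfg, out_cfg, N, max(Q, 200),
                                          selector=selector, model=model,
                                          seed=seed + 1)
    model = estimands.model
    columns = cov_cfg.design_columns
    labels = list(plans)
    children = np.random.SeedSequence(seed).spawn(Q)

    def one(child):
        sub = child.spawn(len(labels) + 1)
        data = dgm.generate_dataset(cov_cfg, out_cfg, N,
                                    np.random.default_rng(sub[0]))
        try:
            gfit = fit_model(data)
        except FitError:
            return None
        out = {}
        mask = np.array([t in set(model) for t in data.term_names])
        for li, lab in enumerate(labels):
            pseed = int(sub[li + 1].generate_state(1)[0] % (2 ** 31))
            plan = plans[lab].with_seed(pseed)
            try:
                ens = resample_and_select(data, plan, selector)
            except ResamplingError:
                out[lab] = None
                continue
            out[lab] = (
                _column_vif(ens),
                float((ens.selected == mask).all(axis=1).mean()),
                rcb_all(ens, gfit),
                rmsdr_all(ens, gfit),
                ens.n_failed,
            )
        return out

    results = _map(one, children, n_jobs)
    results = [r for r in results if r is not None]
    rows = []
    est = estimands.per_term
    for lab in labels:
        per = [r[lab] for r in results if r[lab] is not None]
        n_data_failed = sum(r[lab] is None for r in results)
        if not per:
            continue
        vifs = np.array([p[0] for p in per])     # (Q_ok, p)
        msfs = np.array([p[1] for p in per])
        rcbs = np.array([p[2] for p in per])
        rmsdrs = np.array([p[3] for p in per])
        n_resample_failed = int(sum(p[4] for p in per))
        Q_ok = len(per)
        for j, col in enumerate(columns):
            rows.append(_freq_row("vif", lab, col, vifs[:, j],
                                  est.loc[col, "vif"]))
            rows.append(_bias_row("rcb", lab, col, rcbs[:, j],
                                  est.loc[col, "rcb"]))
            rows.append(_bias_row("rmsdr", lab, col, rmsdrs[:, j],
                                  est.loc[col, "rmsdr"]))
        row = _freq_row("msf", lab, "model", msfs, estimands.msf)
        row["n_datasets"] = Q_ok
        row["n_dataset_failures"] = n_data_failed
        row["n_resample_failures"] = n_resample_failed
        rows.append(row)
    table = pd.DataFrame(rows)
    return PerformanceTable(table=table, estimands=estimands, N=N,
                            Q=len(results), plans=dict(plans))


def _freq_row(measure, scheme, item, x, estimand):
    x = np.asarray(x, dtype=float)
    Q = len(x)
    err = x - estimand
    rmse = float(np.sqrt(np.mean(err ** 2)))
    rmse_mcse = (float(np.std(err ** 2, ddof=1) / np.sqrt(Q) /
                       (2.0 * rmse)) if rmse > 0 and Q > 1 else 0.0)
    return {
        "measure": measure, "scheme": scheme, "item": item,
        "estimand": float(estimand),
        "mean": float(x.mean()),
        "mean_mcse": float(x.std(ddof=1) / np.sqrt(Q)) if Q > 1 else 0.0,
        "rmse": rmse, "rmse_mcse": rmse_mcse,
        "median_bias": float(np.median(err)),
        "median_abs_bias": float(np.median(np.abs(err))),
    }


def _bias_row(measure, scheme, item, x, estimand):
    x = np.asarray(x, dtype=float)
    ok = np.isfinite(x)
    if np.isnan(estimand) or not ok.any():
        # estimand undefined (nonpredictor RCB): report the raw estimates
        med = float(np.nanmedian(x)) if ok.any() else float("nan")
        return {"measure": measure, "scheme": scheme, "item": item,
                "estimand": float("nan"), "mean": float(np.nanmean(x))
                if ok.any() else float("nan"),
                "mean_mcse": float("nan"), "rmse": float("nan"),
                "rmse_mcse": float("nan"), "median_bias": float("nan"),
                "median_abs_bias": float("nan"), "median_estimate": med}
    x = x[ok]
    Q = len(x)
    err = x - estimand
    sd = x.std(ddof=1) if Q > 1 else 0.0
    # MC SE of a median, normal approximation
    med_mcse = float(1.2533 * sd / np.sqrt(Q)) if Q > 1 else 0.0
    return {
        "measure": measure, "scheme": scheme, "item": item,
        "estimand": float(estimand),
        "mean": float(x.mean()),
        "mean_mcse": float(sd / np.sqrt(Q)) if Q > 1 else 0.0,
        "rmse": float(np.sqrt(np.mean(err ** 2))),
        "rmse_mcse": float("nan"),
        "median_bias": float(np.median(err)),
        "median_bias_mcse": med_mcse,
        "median_abs_bias": float(np.median(np.abs(err))),
        "median_estimate": float(np.median(x)),
    }


def _pad_global(gfit, data: Dataset) -> np.ndarray:
    out = np.zeros(data.p)
    idx = {c: j for j, c in enumerate(data.columns)}
    for c, b in zip(gfit.columns, gfit.params):
        out[idx[c]] = b
    return out


def _owner_terms(data: Dataset, columns) -> list:
    owner = {}
    for t in data.term_names:
        for c in data.term_columns(t):
            owner[c] = t
    return [owner[c] for c in columns]


def _ratio_of_rms_mcse(num_dev, den_dev, ratio) -> np.ndarray:
    """Delta-method MC SE of sqrt(mean(a^2))/sqrt(mean(b^2)) per column."""
    Q = num_dev.shape[0]
    a2 = num_dev ** 2
    b2 = den_dev ** 2
    ma, mb = a2.mean(axis=0), b2.mean(axis=0)
    va = a2.var(axis=0, ddof=1) / Q
    vb = b2.var(axis=0, ddof=1) / Q
    cab = np.array([np.cov(a2[:, j], b2[:, j], ddof=1)[0, 1] / Q
                    for j in range(a2.shape[1])])
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_var = va / ma ** 2 + vb / mb ** 2 - 2.0 * cab / (ma * mb)
        return 0.5 * ratio * np.sqrt(np.maximum(rel_var, 0.0))


def _map(fn, items, n_jobs):
    if n_jobs == 1:
        return [fn(it) for it in items]
    from joblib import Parallel, delayed
    return Parallel(n_jobs=n_jobs)(delayed(fn)(it) for it in items)
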