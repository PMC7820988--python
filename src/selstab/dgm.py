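"""Synthetic data generator: Gaussian-latent covariates with mixed marginals.

Covariates are generated from latent standard-normal deviates with a
prespecified correlation matrix, then transformed variable by variable to
realistic marginal distributions (normal, log-normal, exponential,
zero-inflated normal, Bernoulli via latent thresholding, and 3-level
ordinal factors via two thresholds that expand into two dummy columns).

The shipped default configuration emulates a typical medical observational
study: 15 latent variables yielding 17 design columns (nine continuous, six
binary, plus two dummy pairs from the ordinal factors), of which the first
eight (``X1 .. X8``) are true predictors of a continuous outcome with a
global-model R-squared of about 0.47.  See ``docs/methods.md`` for how the
default latent correlation matrix and marginal constants were calibrated.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .data import Dataset
from .exceptions import ConfigError
from ._dgm_default import DEFAULT_LATENT_CORR

KINDS = ("normal", "lognormal", "exponential", "bernoulli",
         "zero_inflated_normal", "ordinal3")


@dataclass(frozen=True)
class VariableSpec:
    """One latent variable and its marginal transform.

    ``ordinal3`` expands into two dummy columns (named ``<name>_2`` and
    ``<name>_3`` unless overridden): ``coding="cumulative"`` gives
    I(level >= 2), I(level = 3); ``coding="indicator"`` gives I(level = 2),
    I(level = 3) against the first level as reference.
    """

    name: str
    kind: str
    params: tuple = ()
    columns: tuple = ()
    coding: str = "cumulative"

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ConfigError(f"unknown marginal kind {self.kind!r}")
        if not self.columns:
            cols = ((f"{self.name}_2", f"{self.name}_3")
                    if self.kind == "ordinal3" else (self.name,))
            object.__setattr__(self, "columns", cols)
        if self.kind == "ordinal3":
            if len(self.params) != 3 or abs(sum(self.params) - 1) > 1e-9:
                raise ConfigError("ordinal3 needs three level probabilities "
                                  "summing to 1")
            if self.coding not in ("cumulative", "indicator"):
                raise ConfigError("ordinal3 coding must be 'cumulative' or "
                                  "'indicator'")
        if self.kind == "bernoulli" and not 0 < self.params[0] < 1:
            raise ConfigError("bernoulli needs 0 < p < 1")

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def transform(self, z: np.ndarray) -> np.ndarray:
        """Map standard-normal deviates to the marginal, column-wise."""
        if self.kind == "normal":
            mu, sd = self.params
            return (mu + sd * z)[:, None]
        if self.kind == "lognormal":
            mu, sd = self.params
            return np.exp(mu + sd * z)[:, None]
        if self.kind == "exponential":
            (scale,) = self.params
            u = np.clip(stats.norm.cdf(z), 1e-16, 1 - 1e-16)
            return (-scale * np.log1p(-u))[:, None]
        if self.kind == "bernoulli":
            (p,) = self.params
            # threshold at the upper-p quantile of the standard normal
            return (z > stats.norm.ppf(1.0 - p)).astype(float)[:, None]
        if self.kind == "zero_inflated_normal":
            p0, mu, sd = self.params
            u = np.clip(stats.norm.cdf(z), 1e-16, 1 - 1e-16)
            out = np.zeros_like(z)
            m = u > p0
            out[m] = mu + sd * stats.norm.ppf((u[m] - p0) / (1.0 - p0))
            return out[:, None]
        # ordinal3
        p1, p2, _ = self.params
        t1, t2 = stats.norm.ppf(p1), stats.norm.ppf(p1 + p2)
        ge2 = z > t1
        eq3 = z > t2
        first = ge2 if self.coding == "cumulative" else (ge2 & ~eq3)
        return np.column_stack([first, eq3]).astype(float)


@dataclass(frozen=True)
class CovariateConfig:
    """Latent dimension, correlation matrix, and per-variable transforms."""

    variables: tuple
    latent_corr: np.ndarray = field(repr=False)

    def __post_init__(self):
        R = np.asarray(self.latent_corr, dtype=float)
        L = len(self.variables)
        if R.shape != (L, L):
            raise ConfigError(f"latent correlation matrix must be "
                              f"{L}x{L}, got {R.shape}")
        if not np.allclose(R, R.T, atol=1e-10):
            raise ConfigError("latent correlation matrix must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-10):
            raise ConfigError("latent correlation matrix must have unit "
                              "diagonal")
        w = np.linalg.eigvalsh(R)
        if w.min() <= 1e-10:
            raise ConfigError(
                f"latent correlation matrix is not positive definite "
                f"(smallest eigenvalue {w.min():.3e})")
        object.__setattr__(self, "latent_corr", R)

    @property
    def latent_dim(self) -> int:
        return len(self.variables)

    @property
    def design_columns(self) -> tuple:
        return tuple(c for v in self.variables for c in v.columns)

    def cholesky(self) -> np.ndarray:
        return np.linalg.cholesky(self.latent_corr)

    def config_hash(self) -> str:
        payload = json.dumps(
            [[v.name, v.kind, list(v.params), list(v.columns), v.coding]
             for v in self.variables]
            + [np.round(self.latent_corr, 10).tolist()])
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class OutcomeConfig:
    """True outcome model on the design columns.

    ``beta`` holds the nonzero true coefficients by column name; columns
    absent from it are nonpredictors.  ``sigma_eps`` is the linear-model
    noise SD; ``intercept`` the logistic intercept; ``baseline_hazard`` and
    ``censoring_rate`` parameterize exponential event and censoring times
    for the Cox family.
    """

    family: str = "linear"
    beta: dict = field(default_factory=dict)
    sigma_eps: float = 0.93
    intercept: float = 0.0
    baseline_hazard: float = 0.10
    censoring_rate: float = 0.10

    def beta_vector(self, columns) -> np.ndarray:
        unknown = set(self.beta) - set(columns)
        if unknown:
            raise ConfigError(f"beta names not among design columns: "
                              f"{sorted(unknown)}")
        return np.array([self.beta.get(c, 0.0) for c in columns])

    def predictor_columns(self, columns) -> tuple:
        return tuple(c for c in columns if self.beta.get(c, 0.0) != 0.0)


def generate_covariates(cfg: CovariateConfig, N: int, seed) -> pd.DataFrame:
    """Draw N rows of design covariates as a data frame."""
    rng = _as_rng(seed)
    return pd.DataFrame(_covariate_matrix(cfg, N, rng),
                        columns=list(cfg.design_columns))


def _covariate_matrix(cfg: CovariateConfig, N: int,
                      rng: np.random.Generator) -> np.ndarray:
    Z = rng.standard_normal((N, cfg.latent_dim)) @ cfg.cholesky().T
    parts = [v.transform(Z[:, l]) for l, v in enumerate(cfg.variables)]
    return np.hstack(parts)


def generate_outcome(X, cfg: OutcomeConfig, seed):
    """Generate the outcome for a covariate table.

    linear: ``Y = X beta + eps`` with iid Gaussian noise; logistic:
    ``P(Y=1) = expit(intercept + X beta)``; cox: exponential event times
    with hazard ``baseline_hazard * exp(X beta)`` under independent
    exponential censoring — returns ``(time, event)`` for cox, else ``y``.
    """
    rng = _as_rng(seed)
    if isinstance(X, pd.DataFrame):
        columns = tuple(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        raise ConfigError("generate_outcome expects a DataFrame; use "
                          "generate_dataset for the array path")
    lp = X @ cfg.beta_vector(columns)
    return _outcome_from_lp(lp, cfg, rng)


def _outcome_from_lp(lp, cfg, rng):
    N = len(lp)
    if cfg.family == "linear":
        return lp + rng.normal(0.0, cfg.sigma_eps, N)
    if cfg.family == "logistic":
        return (rng.random(N) < expit(cfg.intercept + lp)).astype(float)
    if cfg.family == "cox":
        T = rng.exponential(1.0, N) / (cfg.baseline_hazard * np.exp(lp))
        if cfg.censoring_rate > 0:
            C = rng.exponential(1.0 / cfg.censoring_rate, N)
        else:
            C = np.full(N, np.inf)
        return np.minimum(T, C), (T <= C).astype(float)
    raise ConfigError(f"unknown family {cfg.family!r}")


def generate_dataset(cov_cfg: CovariateConfig, out_cfg: OutcomeConfig,
                     N: int, seed, grouped_terms: bool = False) -> Dataset:
    """Generate a ready-to-fit :class:`Dataset`.

    ``grouped_terms=True`` makes each ordinal factor's dummy pair one
    multi-column term; the default treats every design column as its own
    term (the convention used throughout the simulation engine).
    """
    rng = _as_rng(seed)
    X = _covariate_matrix(cov_cfg, N, rng)
    columns = cov_cfg.design_columns
    lp = X @ out_cfg.beta_vector(columns)
    out = _outcome_from_lp(lp, out_cfg, rng)
    terms = {}
    j = 0
    for v in cov_cfg.variables:
        if grouped_terms:
            terms[v.name] = list(range(j, j + v.n_columns))
        else:
            for c in v.columns:
                terms[c] = [j + v.columns.index(c)]
        j += v.n_columns
    if out_cfg.family == "cox":
        time, event = out
        return Dataset(X, time, terms, "cox", columns=columns, event=event)
    return Dataset(X, out, terms, out_cfg.family, columns=columns)


def save_dataset(data: Dataset, path, *, seed=None,
                 cov_cfg: CovariateConfig | None = None) -> None:
    """Write a generated dataset as CSV plus a JSON metadata sidecar."""
    df = data.to_dataframe()
    df.to_csv(path, index=False)
    meta = {"family": data.family, "N": data.n, "seed": seed,
            "config_hash": None if cov_cfg is None else cov_cfg.config_hash()}
    with open(f"{path}.meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)


# ---------------------------------------------------------------------------
# the default study configuration


def default_covariate_config() -> CovariateConfig:
    """The default 15-latent / 17-column covariate structure.

    Marginal constants are calibrated so each variable's SD matches its
    standardized-to-raw coefficient ratio in the default outcome model; the
    latent correlation matrix (entries in [-0.3, 0.8]) is calibrated so each
    design column's multiple R-squared on the other sixteen matches the
    target profile, with X6, X15 and X17 exactly independent of everything.
    """
    variables = (
        VariableSpec("X1", "normal", (50.0, 10.0)),
        VariableSpec("X2", "normal", (0.0, 0.37)),
        VariableSpec("X3", "zero_inflated_normal", (0.3, 1.5, 1.695)),
        VariableSpec("X4", "normal", (0.0, 0.399)),
        VariableSpec("X5", "bernoulli", (0.4,)),
        VariableSpec("X6", "lognormal", (1.327, 1.0)),
        VariableSpec("X7", "bernoulli", (0.7,)),
        VariableSpec("X8", "normal", (0.0, 10.44)),
        # ordinal factor A: levels (0.3, 0.5, 0.2) -> X9 = I(level>=2),
        # X10 = I(level=3), marginals 0.7 / 0.2
        VariableSpec("A", "ordinal3", (0.3, 0.5, 0.2),
                     columns=("X9", "X10"), coding="cumulative"),
        VariableSpec("X11", "exponential", (1.0,)),
        # ordinal factor Bf: levels (0.7, 0.2, 0.1) -> X12 = I(level=2),
        # X13 = I(level=3), marginals 0.2 / 0.1
        VariableSpec("Bf", "ordinal3", (0.7, 0.2, 0.1),
                     columns=("X12", "X13"), coding="indicator"),
        VariableSpec("X14", "normal", (0.0, 1.0)),
        VariableSpec("X15", "normal", (0.0, 1.0)),
        VariableSpec("X16", "bernoulli", (0.5,)),
        VariableSpec("X17", "bernoulli", (0.5,)),
    )
    return CovariateConfig(variables=variables,
                           latent_corr=DEFAULT_LATENT_CORR.copy())


#: True coefficients of the default continuous outcome (X9..X17 are null).
DEFAULT_BETA = {
    "X1": 0.040, "X2": -1.040, "X3": 0.250, "X4": 0.624,
    "X5": 0.402, "X6": 0.021, "X7": -0.398, "X8": -0.009,
}


def default_outcome_config(family: str = "linear") -> OutcomeConfig:
    return OutcomeConfig(family=family, beta=dict(DEFAULT_BETA),
                         sigma_eps=0.93)


def calibrate_noise_sd(cov_cfg: CovariateConfig, beta: dict,
                       target_r2: float = 0.47, N: int = 200_000,
                       seed: int = 0) -> float:
    """Noise SD that yields the target global R-squared on a large sample."""
    rng = _as_rng(seed)
    X = _covariate_matrix(cov_cfg, N, rng)
    lp = X @ OutcomeConfig(beta=dict(beta)).beta_vector(
        cov_cfg.design_columns)
    var_lp = float(np.var(lp))
    return float(np.sqrt(var_lp * (1.0 - target_r2) / target_r2))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
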