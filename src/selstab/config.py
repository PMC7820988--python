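"""End-user run configuration and the one-call ``assess`` entry point.

A :class:`RunConfig` describes a complete stability assessment: the input
CSV, the outcome and term structure, the selector, and the two resampling
plans — by default subsampling with m = 0.5N for the frequency measures and
the bootstrap for RCB/RMSDR.  ``assess`` validates everything before any
computation, runs the assessment, and writes the report atomically (no
partial outputs on failure).
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .data import Dataset, read_dataset
from .exceptions import ConfigError
from .resampling import ResamplePlan
from .selection import ALPHA_AIC
from .stability import StabilityReport, stability_report


@dataclass
class RunConfig:
    """Everything needed to reproduce one stability assessment."""

    data: str
    family: str = "linear"
    outcome: str | None = None
    time: str | None = None
    event: str | None = None
    terms: dict | None = None
    covariates: list | None = None
    alpha: float = ALPHA_AIC
    forced_terms: tuple = ()
    inclusion: dict = field(default_factory=lambda: {
        "scheme": "subsample", "proportion": 0.5, "B": 1000})
    bias: dict = field(default_factory=lambda: {
        "scheme": "bootstrap", "B": 1000})
    seed: int = 1
    outdir: str = "stability_out"
    verbosity: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "forced_terms" in raw:
            raw["forced_terms"] = tuple(raw["forced_terms"])
        return cls(**raw)

    def plans(self) -> tuple:
        """The two resampling plans, seeded from the run seed."""
        def build(spec, offset):
            spec = dict(spec)
            spec.setdefault("seed", self.seed + offset)
            try:
                return ResamplePlan(**spec)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"invalid resampling plan {spec}: "
                                  f"{exc}") from exc
        return build(self.inclusion, 1), build(self.bias, 2)

    def load(self) -> Dataset:
        if not Path(self.data).exists():
            raise ConfigError(f"input file not found: {self.data}")
        return read_dataset(self.data, family=self.family,
                            outcome=self.outcome, time=self.time,
                            event=self.event, terms=self.terms,
                            covariates=self.covariates)


def assess(cfg: RunConfig) -> StabilityReport:
    """Run a full stability assessment and write the report files.

    Outputs (in ``cfg.outdir``): ``report.csv`` / ``report.json`` (the
    Table-style per-term report), ``top_models.csv`` and ``pairwise.csv``.
    Files are staged in a temporary directory and moved into place only
    after all of them were written.
    """
    inclusion_plan, bias_plan = cfg.plans()   # validate before any work
    data = cfg.load()
    if not 0.0 < cfg.alpha <= 1.0:
        raise ConfigError("alpha must be in (0, 1]")
    bad = set(cfg.forced_terms) - set(data.term_names)
    if bad:
        raise ConfigError(f"forced terms not in data: {sorted(bad)}")

    report = stability_report(data, alpha=cfg.alpha,
                              forced_terms=cfg.forced_terms,
                              inclusion_plan=inclusion_plan,
                              bias_plan=bias_plan)
    report.meta["seed"] = cfg.seed
    report.meta["input"] = str(cfg.data)

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with tempfile.TemporaryDirectory(dir=outdir) as tmp:
        tmp = Path(tmp)
        report.to_csv(tmp / "report.csv")
        report.to_json(tmp / "report.json")
        report.model_frequencies.to_csv(tmp / "top_models.csv", index=False,
                                        float_format="%.6g")
        report.pairwise.to_csv(tmp / "pairwise.csv", float_format="%.6g")
        for name in ("report.csv", "report.json", "top_models.csv",
                     "pairwise.csv"):
            os.replace(tmp / name, outdir / name)
    return report
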