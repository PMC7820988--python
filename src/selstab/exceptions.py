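"""Exception hierarchy.

All package-specific errors derive from :class:`SelstabError` so callers can
catch everything from one base.  Fitting problems (rank deficiency, perfect
separation, non-convergence) derive from :class:`FitError`; during resampling
they are counted as resample failures instead of aborting the run.
"""


class SelstabError(Exception):
    """Base class for all selstab errors."""


class ConfigError(SelstabError):
    """Invalid user configuration (bad column names, malformed YAML, ...)."""


class FitError(SelstabError):
    """A model could not be fitted on the given data."""


class SingularDesignError(FitError):
    """The design matrix of the requested model is rank deficient."""


class SeparationError(FitError):
    """Perfect separation in logistic regression: no finite ML estimate."""


class EliminationError(SelstabError):
    """A refit failed part-way through backward elimination.

    Carries the partial elimination ``trace`` accumulated before the failure.
    """

    def __init__(self, message, trace=()):
        super().__init__(message)
        self.trace = tuple(trace)


class ResamplingError(SelstabError):
    """Resampling could not produce a usable ensemble (e.g. >50% failures)."""
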