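"""Exception hierarchy shared across the package."""


class MistratError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MistratError, ValueError):
    """A configuration object is internally inconsistent or out of range."""


class CalibrationError(MistratError, RuntimeError):
    """An intercept or effect-size calibration could not reach its target."""


class DegenerateStratumError(MistratError, RuntimeError):
    """An exposure stratum is too small to support its imputation models."""


class ImputationError(MistratError, RuntimeError):
    """A univariate imputation model could not produce valid draws."""


class EstimationError(MistratError, RuntimeError):
    """The analysis model could not be fitted (e.g. too few complete cases)."""


class PoolingError(MistratError, ValueError):
    """Rubin's rules pooling received an invalid set of estimates."""


class SummaryError(MistratError, ValueError):
    """Performance summarisation received too few replicate records."""
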