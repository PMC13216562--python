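"""Exception hierarchy shared across the package."""


class TruthSDTError(Exception):
    """Base class for all package errors."""


class ValidationError(TruthSDTError, ValueError):
    """Invalid data passed to an operation (out-of-range, missing, malformed)."""


class ConfigurationError(TruthSDTError, ValueError):
    """Invalid configuration (non-PSD correlation target, bad counts, ...)."""


class UndefinedReliabilityError(TruthSDTError, ValueError):
    """Reliability is undefined (zero total variance across items/parcels)."""


class UndefinedCorrelationError(TruthSDTError, ValueError):
    """Correlation is undefined (zero variance in an input vector)."""


class DegenerateCovariateError(TruthSDTError, ValueError):
    """Partial correlation undefined: covariate collinear with an input."""


class CollinearityError(TruthSDTError, ValueError):
    """Design matrix is rank deficient."""
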