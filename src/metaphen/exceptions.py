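"""Exception hierarchy shared across the package."""


class MetaphenError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MetaphenError, ValueError):
    """A simulation or analysis configuration is invalid.

    The message names the offending field.
    """


class DataError(MetaphenError, ValueError):
    """Input data violate a structural precondition (units, labels, shapes)."""


class PeriodError(DataError):
    """A required measurement period is missing or too short."""


class DegenerateInputError(DataError):
    """The computation is undefined on this input (zero denominator,
    singular design, empty segment, ...)."""


class QualityWarning(UserWarning):
    """Data-quality issue that was repaired (clamped/floored) rather than fatal."""
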