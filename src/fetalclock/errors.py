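"""Exception hierarchy.

Every failure mode raised by the package derives from :class:`FetalClockError`
so callers (and the CLI) can distinguish domain errors from programming bugs.
"""


class FetalClockError(Exception):
    """Base class for all fetalclock errors."""


class InvalidMeasurementError(FetalClockError):
    """A biometric measurement is non-positive or non-finite."""


class SchemaError(FetalClockError):
    """A required CSV column is missing or misnamed."""


class DuplicateScanError(FetalClockError):
    """Two rows share the same (fetus_id, visit_index)."""


class ParseError(FetalClockError):
    """A field could not be parsed; carries the offending row number."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class ConfigError(FetalClockError):
    """An invalid configuration value."""


class DomainError(FetalClockError):
    """A gestational age outside the supported range of a growth curve."""


class DegenerateDataError(FetalClockError):
    """Data with no usable variation (e.g. a constant measure)."""


class InsufficientDataError(FetalClockError):
    """Not enough observations for the requested operation."""


class EmbeddingQualityError(FetalClockError):
    """The spectral embedding does not resolve a monotone clock."""


class NumericalError(FetalClockError):
    """An eigensolver or optimisation failure; carries diagnostics."""


class EmptySummaryError(FetalClockError):
    """No eligible observations were available to summarise."""


class UndefinedFractionError(FetalClockError):
    """A variance ratio whose denominator is (numerically) zero."""
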