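"""Exception hierarchy shared across the package."""


class EmsragError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EmsragError):
    """Invalid configuration value (empty vocabulary, bad chunk sizes, ...)."""


class SchemaError(EmsragError):
    """A table file is missing a required column."""


class ReferentialError(EmsragError):
    """A child table references a stay_id absent from edstays."""


class DimensionError(EmsragError):
    """Requested projection dimension exceeds what the data supports."""


class NormalizationError(EmsragError):
    """A zero vector cannot be L2-normalized."""


class UnswappableClusterError(EmsragError):
    """A cluster/pool has no alternative value to swap to."""


class TemplateError(EmsragError):
    """A prompt template contains an unresolved placeholder."""


class BackendError(EmsragError):
    """A text backend rejected or failed a request."""


class ParseError(EmsragError):
    """A backend reply could not be parsed; carries the raw reply."""

    def __init__(self, message: str, raw_reply: str = ""):
        super().__init__(message)
        self.raw_reply = raw_reply


class CoverageError(EmsragError):
    """A ground-truth item or feature has no matching answer record."""


class UndefinedMetricError(EmsragError):
    """A metric denominator is zero."""


class DegenerateTestError(EmsragError):
    """A statistical test has no information (all differences zero, ...)."""
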