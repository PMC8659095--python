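"""Exception hierarchy shared across the package."""


class ScreenAuditError(Exception):
    """Base class for all package errors."""


class SchemaError(ScreenAuditError):
    """A required column or field is missing or misnamed."""


class ParseError(ScreenAuditError):
    """A value could not be parsed; the message names the offending row(s)."""


class IntegrityError(ScreenAuditError):
    """Data violate a structural invariant (duplicate keys, missing labels...)."""


class InputError(ScreenAuditError):
    """An input file is unusable as a whole (e.g. zero parsable records)."""


class DomainError(ScreenAuditError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class UndefinedMetricError(DomainError):
    """The requested metric is undefined for this input (e.g. single-class labels)."""


class ConfigError(ScreenAuditError):
    """An invalid configuration field; the message names the field."""
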