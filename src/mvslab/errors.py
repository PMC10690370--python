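"""Exception hierarchy for mvslab.

Every error raised by the library derives from :class:`MVSError`, so callers
can catch the whole family with one clause.  The command-line layer maps the
subclasses onto distinct exit codes.
"""


class MVSError(Exception):
    """Base class for all mvslab errors."""


class InvalidParameterError(MVSError, ValueError):
    """A physical or numerical parameter is outside its valid domain."""


class FieldRangeError(MVSError, ValueError):
    """A requested field strength or position is outside the field map."""


class IntegrationError(MVSError, RuntimeError):
    """The ODE integration produced a non-finite state."""


class CalibrationError(MVSError, RuntimeError):
    """The stimulus-gain calibration target cannot be bracketed or met."""


class UnsupportedInputError(MVSError, ValueError):
    """Input data do not meet the minimum requirements (e.g. sampling rate)."""


class EventNotFoundError(MVSError, RuntimeError):
    """Entry/exit events could not be located in a magnetometer trace."""


class WindowError(MVSError, ValueError):
    """A summary window does not fit inside the recorded trace."""


class DesignError(MVSError, ValueError):
    """The statistical design is rank deficient or otherwise unusable."""


class InsufficientDataError(MVSError, ValueError):
    """Too few observations for the requested fit."""


class SchemaError(MVSError, ValueError):
    """A run configuration fails schema validation."""


class MappingError(MVSError, ValueError):
    """External data columns cannot be mapped onto the recording schema."""
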