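"""Exception hierarchy shared across the package.

``ValidationError`` subclasses map to CLI exit code 2, everything else
raised by the library maps to exit code 3.
"""


class MethclockError(Exception):
    """Base class for all package errors."""


class ValidationError(MethclockError, ValueError):
    """Invalid user input: bad domains, malformed files, bad configs."""


class DomainError(ValidationError):
    """A numeric argument outside its mathematical domain."""


class ConfigError(ValidationError):
    """An inconsistent or incomplete configuration."""


class FormatError(ValidationError):
    """A file that does not conform to the documented on-disk format."""


class LeakageError(ValidationError):
    """Train/test sample overlap where disjointness is required."""


class ComputationError(MethclockError):
    """A well-formed request that fails numerically (degenerate data etc.)."""


class PipelineStageError(ComputationError):
    """Wraps a failure inside a named pipeline stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
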