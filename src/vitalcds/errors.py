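"""Exception hierarchy.

Validation-class errors map to CLI exit code 2, I/O-class errors to exit
code 3; everything else is a programming error and surfaces as a traceback.
"""


class VitalCDSError(Exception):
    """Base class for all package errors."""


class ValidationError(VitalCDSError):
    """Input failed a contract check (exit code 2 at the CLI)."""


class ConfigurationError(ValidationError):
    """Bad configuration value or unknown option name."""


class SchemaError(ValidationError):
    """Feature-vector dimension or record schema mismatch."""


class MalformedStreamError(ValidationError):
    """Stream rows with inconsistent channel counts or unparseable values."""


class StreamOrderingError(ValidationError):
    """Timestamps not strictly increasing."""


class DuplicateRecordError(ValidationError):
    """Record ID already registered in the store."""


class MetricMatrixError(ValidationError):
    """Metric matrix is not symmetric positive semidefinite."""


class StoreIOError(VitalCDSError):
    """Storage-layer failure (exit code 3 at the CLI)."""


class UnknownPointerError(StoreIOError):
    """Pointer value absent from the mapping table."""


class StorageCorruptionError(StoreIOError):
    """A mapping-table address does not resolve to a readable record."""
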