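"""Exception hierarchy.

Validation failures (bad inputs, broken invariants) are distinguished from
I/O failures so the CLI can map them to distinct exit codes.
"""


class AlarmSieveError(Exception):
    """Base class for all package errors."""


class ValidationError(AlarmSieveError, ValueError):
    """Raised when an input violates a documented precondition or invariant."""


class DataIOError(AlarmSieveError, IOError):
    """Raised when a record or manifest cannot be read or written."""
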