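"""Exception hierarchy.

``ValidationError`` and its subclasses map to CLI exit code 1 (bad inputs or
parameters); every other :class:`NetmarkError` maps to exit code 2 (runtime
failure).
"""


class NetmarkError(Exception):
    """Base class for all netmark errors."""

    exit_code = 2


class ValidationError(NetmarkError):
    """Invalid parameter or malformed input."""

    exit_code = 1


class SchemaError(ValidationError):
    """A required column or field is missing from a table."""


class InsufficientReplicationError(ValidationError):
    """A group has fewer than two samples; no variance can be estimated."""


class DegenerateLabelsError(ValidationError):
    """Only one class present where two are required."""


class InfeasibleModuleError(NetmarkError):
    """No connected subgraph of the requested size exists."""


class MissingStatisticError(NetmarkError):
    """A node was scored without a z-statistic being available."""


class GeneLookupError(NetmarkError):
    """A requested gene is absent from the expression matrix."""


class FitFailureError(NetmarkError):
    """An iterative fit failed to converge even after the ridge fallback."""
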