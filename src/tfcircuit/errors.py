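"""Exception hierarchy shared across the package.

Validation problems (bad files, mismatched universes, out-of-range
parameters) are distinguished from numerical/computation failures so the
command-line layer can map them to stable exit codes (2 vs 3).
"""


class TFCircuitError(Exception):
    """Base class for all package errors."""


class ValidationError(TFCircuitError, ValueError):
    """Raised when inputs violate a documented precondition or invariant."""


class ComputationError(TFCircuitError, RuntimeError):
    """Raised when a numerical routine fails (e.g. loss of positive-definiteness)."""
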