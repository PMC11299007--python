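"""Structured exceptions with machine-readable codes.

Every error carries a stable ``code`` string and the process exit status the
CLI maps it to (2 = validation, 3 = complete conflict, 4 = I/O).
"""

from __future__ import annotations


class EviFuseError(Exception):
    """Base class for all library errors."""

    code: str = "error"
    exit_code: int = 1


class ValidationError(EviFuseError):
    """Input data violates a structural or numeric constraint."""

    code = "validation"
    exit_code = 2


class DimensionMismatchError(ValidationError):
    """Evidence, weight and frame dimensions do not line up."""

    code = "dimension-mismatch"


class UnknownAlgorithmError(ValidationError):
    """Algorithm tag not one of the recognized fusion rules."""

    code = "unknown-algorithm"


class CompleteConflictError(EviFuseError):
    """Two bodies of evidence place all mass on disjoint propositions.

    The normalizing denominator is zero, so the combination is undefined;
    we refuse rather than return NaN.
    """

    code = "complete-conflict"
    exit_code = 3

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


class DegenerateStateError(EviFuseError):
    """All mass sits in the weight remainder; final beliefs are undefined."""

    code = "degenerate-state"
    exit_code = 2


class InputFormatError(EviFuseError):
    """A file could not be read or does not follow the template."""

    code = "input-format"
    exit_code = 4
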