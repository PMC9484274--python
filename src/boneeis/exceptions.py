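"""Exception hierarchy for boneeis.

All argument/contract violations raise :class:`InvalidArgumentError` (a
``ValueError``) so callers can catch one base type; file-format problems
raise :class:`FormatError` so the CLI can map them to a distinct exit code.
"""


class BoneEISError(Exception):
    """Base class for all boneeis-specific errors."""


class InvalidArgumentError(BoneEISError, ValueError):
    """An argument violates a documented precondition."""


class InsufficientDataError(InvalidArgumentError):
    """Too few data points to perform the requested operation."""


class DegenerateDataError(InvalidArgumentError):
    """Input is degenerate (e.g. zero total variance, equal densities)."""


class FormatError(BoneEISError, ValueError):
    """A file does not conform to one of the documented formats."""
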