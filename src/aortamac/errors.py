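"""Typed errors raised across the pipeline.

Every error the CLI can surface maps onto one of these classes so that
subcommands can exit nonzero with a meaningful message instead of a
traceback.
"""


class AortamacError(Exception):
    """Base class for all package errors."""


class GeometryError(AortamacError):
    """Phantom or mask geometry is inconsistent (disc off-grid, shape mismatch)."""


class InputError(AortamacError):
    """Malformed or inconsistent input data (volumes, tables, labels)."""


class DegenerateReferenceError(AortamacError):
    """Lumen reference zone too small to estimate mean/SD."""


class DegenerateSliceError(AortamacError):
    """A slice whose aorta mask is empty cannot be unfurled."""


class UndefinedScoreError(AortamacError):
    """Wall calcification percentage requested over zero wall area."""


class UnscorableProfileError(AortamacError):
    """Risk profile lacks age or sex and cannot be scored."""


class AnalysisError(AortamacError):
    """A statistical routine was asked for an undefined quantity."""
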