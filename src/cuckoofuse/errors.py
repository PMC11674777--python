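"""Typed exceptions raised across the package.

Every validation failure names the offending row, column or field so batch
pipelines can report precisely what broke; nothing is silently repaired.
"""


class CuckooFuseError(Exception):
    """Base class for all package errors."""


class FormatError(CuckooFuseError):
    """A delimited-text file does not match the expected header/column layout."""


class ValidationError(CuckooFuseError):
    """An in-memory object violates one of its invariants."""


class AlignmentError(CuckooFuseError):
    """Two prediction sets cannot be fused because their samples disagree."""

    def __init__(self, report):
        self.report = report
        super().__init__(f"prediction sets are not aligned: {report.summary()}")


class DimensionError(CuckooFuseError):
    """A shape or length mismatch between related arrays."""


class ParameterError(CuckooFuseError):
    """An out-of-range algorithm parameter."""


class InfeasibilityError(CuckooFuseError):
    """A resampling request cannot be met by the available samples."""


class UndefinedMetricError(CuckooFuseError):
    """A metric has no defined value for the given degenerate input."""


class OptimizationError(CuckooFuseError):
    """The search encountered a non-finite fitness value."""
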