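"""Exception hierarchy shared by all contourdose modules.

Every error raised on a contract violation derives from
:class:`ContourDoseError`, so callers can catch one base class at pipeline
boundaries while tests assert the specific subclass.
"""


class ContourDoseError(Exception):
    """Base class for all contourdose errors."""


class InvalidGridError(ContourDoseError):
    """Grid specification violates its invariants (non-positive spacing, empty shape)."""


class GridMismatchError(ContourDoseError):
    """Two volumes that must share a grid do not."""


class DegenerateContourError(ContourDoseError):
    """A planar contour has fewer than 3 vertices."""


class OutOfExtentError(ContourDoseError):
    """A contour slice or sample point falls outside the grid extent."""


class EmptyStructureError(ContourDoseError):
    """An operation requiring a non-empty structure received an empty mask."""


class UndefinedMetricError(ContourDoseError):
    """A metric is mathematically undefined for the given inputs (e.g. DSC of two empty masks)."""


class InvalidArgumentError(ContourDoseError):
    """A numeric argument is outside its allowed range."""


class PairingError(ContourDoseError):
    """Manual/automatic records cannot be paired (length or case-ID mismatch)."""


class EmptySelectionError(ContourDoseError):
    """A filter selected no records."""


class ConfigurationError(ContourDoseError):
    """Unknown dialect, metric, unit, or malformed configuration field."""


class ParseError(ContourDoseError):
    """A structure or dose file could not be parsed; the message names the offending record."""


class CalibrationError(ContourDoseError):
    """Perturbation calibration could not bracket or reach the requested range."""
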