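"""Exception hierarchy.

Every reader/validator raises a specific subclass of :class:`LamapError`
rather than silently coercing malformed input.
"""


class LamapError(Exception):
    """Base class for all lamap errors."""


class LayoutError(LamapError):
    """Phantom region layout is invalid (overlapping regions, no glass border)."""


class ResolutionError(LamapError):
    """A named region rasterizes to zero pixels at the requested resolution."""


class ParameterError(LamapError):
    """A required (group, region, element) parameter is missing or invalid."""


class FormatError(LamapError):
    """An on-disk artifact violates the documented dialect."""


class AlignmentError(LamapError):
    """Two gridded artifacts that must share geometry do not."""


class DegenerateRangeError(LamapError):
    """8-bit export requested for a constant image (max == min)."""


class CalibrationError(LamapError):
    """Calibration cannot be established (negative slope, missing curve)."""


class RankError(CalibrationError):
    """Standard levels do not span distinct concentrations."""


class NormalizationError(LamapError):
    """Carbon histogram does not separate glass from tissue."""


class DriftEstimationError(LamapError):
    """Too few lines (or degenerate levels) to fit a drift trend."""


class EmptyRoiError(LamapError):
    """A region-of-interest readout was requested for an empty region."""


class PairingError(LamapError):
    """Hemisphere measurements do not belong to the same animal/region/element."""


class CompletenessError(LamapError):
    """Cohort assembly found manifest animals without measurements (or an empty group)."""


class SampleSizeError(LamapError):
    """A statistical test was requested on fewer than two values per group."""


class DomainError(LamapError):
    """An argument is outside the mathematical domain of the operation."""


class ConfigError(LamapError):
    """Pipeline configuration is invalid; raised before any work is done."""
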