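"""Exception and warning types shared across the pipeline."""


class PatlakGfrError(Exception):
    """Base class for all package errors."""


class InsufficientDataError(PatlakGfrError):
    """Too few usable data points for a fit or detection step."""


class CalibrationDomainError(PatlakGfrError):
    """A value lies outside the mathematical domain of the calibration map."""


class BolusNotFoundError(PatlakGfrError):
    """No contrast-arrival threshold crossing found in the aortic curve."""


class RecirculationNotFoundError(PatlakGfrError):
    """No second aortic maximum (recirculation peak) could be detected."""


class FlatCurveError(PatlakGfrError):
    """A curve carries no usable extremum (constant or empty)."""


class DegenerateDenominatorError(PatlakGfrError):
    """All candidate Patlak points were dropped by the denominator guard."""


class WindowTooShortError(PatlakGfrError):
    """The evaluation window contains too few frames for a regression."""


class GridMismatchError(PatlakGfrError):
    """Two curves that must share a time grid do not."""


class SchemaError(PatlakGfrError):
    """An input file does not match the expected column/key schema."""


class PipelineStageError(PatlakGfrError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"pipeline stage '{stage}' failed: {original}")


class PatlakGfrWarning(UserWarning):
    """Base class for all package warnings."""


class CalibrationRangeWarning(PatlakGfrWarning):
    """Signal intensity outside the calibrated validity range; extrapolated."""


class NonMonotoneWarning(PatlakGfrWarning):
    """Dilution SI not monotone in concentration; fit uses the monotone prefix."""


class NegativeValueWarning(PatlakGfrWarning):
    """Negative signal or concentration retained (or clipped) during processing."""


class TruncatedWindowWarning(PatlakGfrWarning):
    """Evaluation window truncated because the series ends early."""


class BoundaryPeakWarning(PatlakGfrWarning):
    """A detected extremum sits on the final frame of the curve."""


class AlreadySubtractedWarning(PatlakGfrWarning):
    """Baseline subtraction requested on an already-subtracted series."""


class UnsmoothedCurveWarning(PatlakGfrWarning):
    """Landmark detection invoked on a curve not flagged as smoothed."""


class NegativeDeltaTWarning(PatlakGfrWarning):
    """Kidney peak preceded the aortic peak; the time shift was floored at 0."""


class UnknownRoiWarning(PatlakGfrWarning):
    """A curve file contains an ROI label the pipeline does not recognise."""


class NonPaperFallbackWarning(PatlakGfrWarning):
    """A configurable fallback without a published counterpart was used."""
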