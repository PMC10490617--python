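"""Exception hierarchy for the wheelfv pipeline.

Every error raised deliberately by the package derives from
:class:`WheelFVError`, so callers batch-processing many sprint files can
catch one type, log, and move on.
"""


class WheelFVError(Exception):
    """Base class for all wheelfv errors."""


class FormatError(WheelFVError):
    """Input file does not match the expected CSV dialect."""


class EmptyTraceError(WheelFVError):
    """Fewer than two valid samples after dropping invalid rows."""


class OrderingError(WheelFVError):
    """Time stamps are not strictly increasing."""


class MetadataError(WheelFVError):
    """Athlete/chair/environment metadata failed validation."""


class NoSprintDetectedError(WheelFVError):
    """No gyroscope sample exceeds the onset threshold."""


class DegenerateSprintError(WheelFVError):
    """Velocity maximum at the first sample; nothing to crop."""


class FilterLengthError(WheelFVError):
    """Series too short for the zero-phase filter's padding."""


class FitFailureError(WheelFVError):
    """Nonlinear least squares did not converge within the restart budget."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DegenerateRegressionError(WheelFVError):
    """Regression input has zero variance (flat velocity or measurement)."""


class UndefinedTestError(WheelFVError):
    """Paired test undefined: too few pairs or zero difference variance."""


class ComparisonError(WheelFVError):
    """Cohort comparison impossible (e.g. only one resistive model present)."""
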