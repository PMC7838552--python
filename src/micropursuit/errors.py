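"""Typed exceptions raised across the package."""


class MicropursuitError(Exception):
    """Base class for all package-specific errors."""


class TooShortError(MicropursuitError):
    """Signal has fewer samples than the operation requires."""


class BadWindowError(MicropursuitError):
    """Invalid differentiation window for the requested method."""


class UpsampleError(MicropursuitError):
    """Requested resampling rate exceeds the source rate."""


class NyquistViolationError(MicropursuitError):
    """Filter cutoff at or above the Nyquist frequency."""


class BadRatioError(MicropursuitError):
    """Lissajous frequency ratio outside the allowed set."""


class InstabilityError(MicropursuitError):
    """Simulated gaze particle escaped the configured radius."""

    def __init__(self, step: int, radius: float):
        self.step = step
        self.radius = radius
        super().__init__(
            f"gaze particle exceeded escape radius {radius:g} deg at step {step}"
        )


class OverlapError(MicropursuitError):
    """Requested saccade injection rate cannot be honored without overlap."""


class EmptyEpochError(MicropursuitError):
    """Epoch contains no valid samples."""


class LengthMismatchError(MicropursuitError):
    """Paired trajectory slices have different lengths."""


class ZeroStimulusMotionError(MicropursuitError):
    """Velocity gain is undefined for a motionless stimulus."""


class DegenerateNoiseError(MicropursuitError):
    """Velocity noise scale is zero; relative thresholds are undefined."""


class WindowMismatchError(MicropursuitError):
    """Binocular epochs do not cover the same time window."""


class TooFewEventsError(MicropursuitError):
    """Not enough (or degenerate) events for a main-sequence fit."""


class IncompleteMatrixError(MicropursuitError):
    """Subject x condition matrix has missing cells."""


class AllZeroDifferencesError(MicropursuitError):
    """All paired differences are zero; signed-rank test undefined."""


class EmptyGroupError(MicropursuitError):
    """A group passed to a rank test is empty."""


class BadArgsError(MicropursuitError):
    """Arguments outside the documented domain."""


class SchemaError(MicropursuitError):
    """Malformed input file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class UnsupportedDialectError(MicropursuitError):
    """ASC file dialect not supported by the subset reader."""
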