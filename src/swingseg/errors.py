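"""Exception hierarchy.

Every error carries a stable machine-readable ``code`` so callers (and the
CLI) can branch on failure modes without parsing messages.
"""

from __future__ import annotations


class SwingSegError(Exception):
    """Base class; ``code`` is a stable snake_case identifier."""

    code = "swingseg_error"

    def __init__(self, message: str = ""):
        super().__init__(message or self.code)


class SchemaError(SwingSegError):
    code = "schema_error"


class TimeError(SwingSegError):
    code = "time_error"


class LabelsOutOfWindow(SwingSegError):
    code = "labels_out_of_window"


class IncompletePhaseSequence(SwingSegError):
    code = "incomplete_phase_sequence"


class DurationError(SwingSegError):
    code = "duration_error"


class UnlabelableTrack(SwingSegError):
    code = "unlabelable_track"


class FilterLengthError(SwingSegError):
    code = "filter_length_error"


class NoJumpPeak(SwingSegError):
    code = "no_jump_peak"


class WindowOutOfRange(SwingSegError):
    code = "window_out_of_range"


class EventNotFound(SwingSegError):
    code = "event_not_found"

    def __init__(self, message: str = "", point: str | None = None):
        self.point = point
        if point and point not in message:
            message = f"{self.code}: {point}" + (f" ({message})" if message else "")
        super().__init__(message)


class OrderViolation(SwingSegError):
    code = "order_violation"


class TrainingDiverged(SwingSegError):
    code = "training_diverged"


class PairingError(SwingSegError):
    code = "pairing_error"


class EmptyFold(SwingSegError):
    code = "empty_fold"


class DegeneratePhase(SwingSegError):
    code = "degenerate_phase"
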