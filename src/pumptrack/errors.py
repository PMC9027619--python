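"""Exception hierarchy for pumptrack.

All library errors derive from :class:`PumptrackError` so callers (and the
CLI) can separate data problems from programming errors.
"""

from __future__ import annotations


class PumptrackError(Exception):
    """Base class for all pumptrack errors."""


class EmptyLogError(PumptrackError):
    """A logfile contained no valid samples."""


class DuplicateConflictError(PumptrackError):
    """Samples share a timestamp but disagree in value.

    Attributes
    ----------
    timestamps : list
        The conflicting timestamps.
    """

    def __init__(self, timestamps):
        self.timestamps = list(timestamps)
        super().__init__(
            f"conflicting duplicate samples at {len(self.timestamps)} "
            f"timestamp(s): {', '.join(str(t) for t in self.timestamps[:5])}"
            + ("..." if len(self.timestamps) > 5 else "")
        )


class EmptySnapshotError(PumptrackError):
    """No samples fall inside the requested event window."""


class SpeedRangeError(PumptrackError):
    """Pump speed outside the expected-power model's valid range."""


class OrderingError(PumptrackError):
    """Samples presented to the tracker out of time order."""


class InsufficientDataError(PumptrackError):
    """Not enough data for the requested computation."""


class UndefinedWarningError(PumptrackError):
    """Early warning requested for a snapshot without any detection."""


class FitError(PumptrackError):
    """Nonlinear fit failed to converge from every start."""


class SynthValidationError(PumptrackError):
    """Invalid synthetic-data generator parameters."""
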