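"""Reading, writing, aggregation and windowing of pump controller logfiles.

A centrifugal-LVAD controller stores one telemetry sample every 15 minutes:
pump set speed (rpm), power consumption (W) and, optionally, current (A) and
estimated flow (L/min).  Logfiles are downloaded at irregular occasions
(check-ups, readmissions), so one patient typically contributes several
overlapping files that must be merged into a single deduplicated log before
analysis.

CSV dialect
-----------
Comma separated with header ``timestamp,speed_rpm,power_w,current_a,flow_lpm``;
timestamps are ISO-8601 at second resolution; the optional columns may be
empty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DuplicateConflictError,
    EmptyLogError,
    EmptySnapshotError,
)

logger = logging.getLogger(__name__)

#: Canonical logfile column order.
LOG_COLUMNS = ["timestamp", "speed_rpm", "power_w", "current_a", "flow_lpm"]

#: Window bounds of a thrombosis snapshot relative to the diagnosis time.
SNAPSHOT_PRE = pd.Timedelta(days=14)
SNAPSHOT_POST = pd.Timedelta(days=1)

#: Minimum spacing between repeat thrombosis events on the same patient for
#: the later event to be analysed (strict inequality).
MIN_EVENT_SPACING = pd.Timedelta(days=14)

#: Minimum duration of a control period; shorter segments are excluded.
MIN_CONTROL_DAYS = 14.0

#: One patient-year of monitored time, in days.
DAYS_PER_PATIENT_YEAR = 365.25

SECONDS_PER_DAY = 86400.0


@dataclass(frozen=True)
class LogSample:
    """One 15-minute telemetry sample."""

    t: pd.Timestamp
    speed: float
    power: float
    current: float | None = None
    est_flow: float | None = None

    def __post_init__(self):
        if pd.isna(self.t):
            raise ValueError("sample timestamp must be finite")
        if self.power < 0:
            raise ValueError(f"negative power {self.power} W")
        if self.speed < 0:
            raise ValueError(f"negative speed {self.speed} rpm")


def _validate_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Normalise a telemetry frame and enforce the log invariants."""
    frame = frame.reset_index(drop=True)
    for col in LOG_COLUMNS:
        if col not in frame.columns:
            frame[col] = np.nan
    frame = frame[LOG_COLUMNS]
    t = frame["timestamp"]
    if t.isna().any():
        raise ValueError("non-finite timestamp in log frame")
    if len(frame) > 1:
        dt = t.diff().iloc[1:]
        if (dt <= pd.Timedelta(0)).any():
            raise ValueError("timestamps must be strictly increasing")
    if (frame["power_w"] < 0).any():
        raise ValueError("negative power in log frame")
    if (frame["speed_rpm"] < 0).any():
        raise ValueError("negative speed in log frame")
    return frame


@dataclass
class PatientLog:
    """A patient's aggregated telemetry stream.

    Parameters
    ----------
    patient_id : str
        Opaque patient identifier.
    frame : pandas.DataFrame
        Columns ``timestamp, speed_rpm, power_w, current_a, flow_lpm`` with
        strictly increasing timestamps.
    nominal_interval : float
        Nominal sampling cadence, seconds (controller default 900 s).
    n_skipped : int
        Malformed rows dropped while parsing the source file(s).
    """

    patient_id: str
    frame: pd.DataFrame
    nominal_interval: float = 900.0
    n_skipped: int = field(default=0, compare=False)

    def __post_init__(self):
        self.frame = _validate_frame(self.frame)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def timestamps(self) -> pd.Series:
        return self.frame["timestamp"]

    @property
    def power(self) -> np.ndarray:
        return self.frame["power_w"].to_numpy(float)

    @property
    def speed(self) -> np.ndarray:
        return self.frame["speed_rpm"].to_numpy(float)

    @property
    def duration_days(self) -> float:
        if len(self.frame) < 2:
            return 0.0
        span = self.frame["timestamp"].iloc[-1] - self.frame["timestamp"].iloc[0]
        return span.total_seconds() / SECONDS_PER_DAY

    def samples(self) -> Iterable[LogSample]:
        for row in self.frame.itertuples(index=False):
            yield LogSample(
                t=row.timestamp,
                speed=float(row.speed_rpm),
                power=float(row.power_w),
                current=None if pd.isna(row.current_a) else float(row.current_a),
                est_flow=None if pd.isna(row.flow_lpm) else float(row.flow_lpm),
            )


@dataclass
class Snapshot:
    """Telemetry window around a pump-thrombosis diagnosis.

    Covers up to 14 days before the diagnosis through 1 day after (both
    boundaries closed).  ``annotation_binary`` is the expert label for whether
    an abnormal power trend was visually observable; ``annotation_trinary``
    refines it to observable / uncertain / absent.
    """

    patient_id: str
    event_time: pd.Timestamp
    frame: pd.DataFrame
    annotation_binary: str | None = None
    annotation_trinary: str | None = None

    def __post_init__(self):
        self.frame = _validate_frame(self.frame)
        self.event_time = pd.Timestamp(self.event_time)
        if pd.isna(self.event_time):
            raise ValueError("event_time must be finite")
        t = self.frame["timestamp"]
        lo, hi = self.event_time - SNAPSHOT_PRE, self.event_time + SNAPSHOT_POST
        if len(t) and (t.iloc[0] < lo or t.iloc[-1] > hi):
            raise ValueError("snapshot samples outside the event window")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def power(self) -> np.ndarray:
        return self.frame["power_w"].to_numpy(float)

    @property
    def speed(self) -> np.ndarray:
        return self.frame["speed_rpm"].to_numpy(float)

    @property
    def timestamps(self) -> pd.Series:
        return self.frame["timestamp"]


@dataclass
class ControlPeriod:
    """A contiguous eligible telemetry segment from a control patient."""

    patient_id: str
    frame: pd.DataFrame

    def __post_init__(self):
        self.frame = _validate_frame(self.frame)
        if self.duration_days < MIN_CONTROL_DAYS:
            raise ValueError(
                f"control period of {self.duration_days:.1f} d is shorter "
                f"than the {MIN_CONTROL_DAYS:.0f}-day minimum"
            )

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def duration_days(self) -> float:
        if len(self.frame) < 2:
            return 0.0
        span = self.frame["timestamp"].iloc[-1] - self.frame["timestamp"].iloc[0]
        return span.total_seconds() / SECONDS_PER_DAY

    @property
    def power(self) -> np.ndarray:
        return self.frame["power_w"].to_numpy(float)

    @property
    def speed(self) -> np.ndarray:
        return self.frame["speed_rpm"].to_numpy(float)

    @property
    def timestamps(self) -> pd.Series:
        return self.frame["timestamp"]


# ---------------------------------------------------------------------------
# parsing / writing


def parse_log(
    source,
    patient_id: str = "unknown",
    nominal_interval: float = 900.0,
    keep_first: bool = False,
) -> PatientLog:
    """Parse a logfile CSV into a :class:`PatientLog`.

    Malformed rows (unparseable timestamp, non-numeric or negative speed or
    power) are skipped; the skip count is logged and recorded on the returned
    log.  Rows are returned sorted by time.  Exact duplicate rows are
    collapsed; duplicates that conflict in value raise
    :class:`~pumptrack.errors.DuplicateConflictError` unless ``keep_first``.

    Raises
    ------
    OSError
        If the file cannot be read.
    EmptyLogError
        If no valid rows survive parsing.
    """
    raw = pd.read_csv(source, dtype=str)
    missing = {"timestamp", "speed_rpm", "power_w"} - set(raw.columns)
    if missing:
        raise EmptyLogError(f"logfile missing required columns: {sorted(missing)}")

    frame = pd.DataFrame(
        {
            "timestamp": pd.to_datetime(raw["timestamp"], errors="coerce", format="ISO8601"),
            "speed_rpm": pd.to_numeric(raw["speed_rpm"], errors="coerce"),
            "power_w": pd.to_numeric(raw["power_w"], errors="coerce"),
            "current_a": pd.to_numeric(raw.get("current_a"), errors="coerce"),
            "flow_lpm": pd.to_numeric(raw.get("flow_lpm"), errors="coerce"),
        }
    )
    ok = (
        frame["timestamp"].notna()
        & frame["speed_rpm"].notna()
        & frame["power_w"].notna()
        & (frame["power_w"] >= 0)
        & (frame["speed_rpm"] >= 0)
    )
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.warning("parse_log(%s): skipped %d malformed row(s)", patient_id, n_skipped)
    frame = frame[ok].sort_values("timestamp", kind="stable")
    if frame.empty:
        raise EmptyLogError(f"no valid samples in logfile for patient {patient_id!r}")
    frame = _dedupe(frame, keep_first=keep_first)
    return PatientLog(patient_id, frame, nominal_interval, n_skipped=n_skipped)


def write_log(log: PatientLog | Snapshot | ControlPeriod, path) -> None:
    """Write a telemetry frame in the canonical logfile CSV dialect.

    Timestamps at second resolution, numeric channels at 3 decimals — the
    same resolution the generator uses, so generated logs round-trip.
    """
    out = log.frame.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False, float_format="%.3f")


def _dedupe(frame: pd.DataFrame, keep_first: bool = False) -> pd.DataFrame:
    """Collapse exact-timestamp duplicates; flag value conflicts."""
    if frame["timestamp"].is_unique:
        return frame.reset_index(drop=True)
    deduped = frame.drop_duplicates(keep="first")
    dup_ts = deduped["timestamp"][deduped["timestamp"].duplicated()].unique()
    if len(dup_ts):
        if not keep_first:
            raise DuplicateConflictError(dup_ts)
        logger.warning(
            "keeping first of conflicting duplicates at %d timestamp(s)", len(dup_ts)
        )
        deduped = deduped.drop_duplicates(subset="timestamp", keep="first")
    return deduped.reset_index(drop=True)


def aggregate_logs(
    logs: Sequence[PatientLog], keep_first: bool = False
) -> PatientLog:
    """Merge several logfiles from one patient into a single aggregated log.

    The union of samples is taken, exact-timestamp duplicates are collapsed
    to one sample and the result is sorted.  Duplicates whose values disagree
    raise :class:`~pumptrack.errors.DuplicateConflictError` (downgrade to a
    warning with ``keep_first=True``): the deduplication rule is only defined
    for true duplicates, so conflicts fail loudly by default.
    """
    if not logs:
        raise EmptyLogError("no logs to aggregate")
    pids = {log.patient_id for log in logs}
    if len(pids) != 1:
        raise ValueError(f"aggregate_logs mixes patients: {sorted(pids)}")
    merged = pd.concat([log.frame for log in logs], ignore_index=True)
    merged = merged.sort_values("timestamp", kind="stable")
    merged = _dedupe(merged, keep_first=keep_first)
    return PatientLog(logs[0].patient_id, merged, logs[0].nominal_interval)


# ---------------------------------------------------------------------------
# windowing


def extract_snapshot(
    log: PatientLog,
    event_time,
    annotation_binary: str | None = None,
    annotation_trinary: str | None = None,
) -> Snapshot:
    """Cut the [event − 14 d, event + 1 d] window around a diagnosis.

    Both window boundaries are closed; a sample exactly at ``event_time`` is
    counted on the pre-diagnosis side by the evaluation module.
    """
    if len(log) == 0:
        raise EmptyLogError("cannot extract snapshot from empty log")
    event_time = pd.Timestamp(event_time)
    t = log.frame["timestamp"]
    mask = (t >= event_time - SNAPSHOT_PRE) & (t <= event_time + SNAPSHOT_POST)
    window = log.frame[mask]
    if window.empty:
        raise EmptySnapshotError(
            f"no samples within [{event_time - SNAPSHOT_PRE}, "
            f"{event_time + SNAPSHOT_POST}] for patient {log.patient_id!r}"
        )
    return Snapshot(
        patient_id=log.patient_id,
        event_time=event_time,
        frame=window,
        annotation_binary=annotation_binary,
        annotation_trinary=annotation_trinary,
    )


def validate_event_spacing(event_times: Sequence) -> list[pd.Timestamp]:
    """Filter repeat thrombosis events closer than 14 days apart.

    The first event is always kept; each later event is kept iff its gap to
    the previously *kept* event is strictly greater than 14 days.
    """
    events = [pd.Timestamp(t) for t in event_times]
    if sorted(events) != events:
        raise ValueError("event times must be sorted ascending")
    kept: list[pd.Timestamp] = []
    for ev in events:
        if not kept or ev - kept[-1] > MIN_EVENT_SPACING:
            kept.append(ev)
    return kept


def segment_control_periods(
    log: PatientLog,
    eligible_windows: Sequence[tuple],
    min_days: float = MIN_CONTROL_DAYS,
    gap_tolerance: float | None = None,
) -> list[ControlPeriod]:
    """Split an eligible control log into contiguous periods of ≥ 14 days.

    ``eligible_windows`` are non-overlapping (start, end) intervals in which
    the patient met the clinical control criteria (screened upstream, supplied
    as data).  Within each window the log is split wherever the telemetry gap
    exceeds ``gap_tolerance`` (default 4 × nominal cadence = 1 h), and
    segments shorter than ``min_days`` are dropped.
    """
    if gap_tolerance is None:
        gap_tolerance = 4.0 * log.nominal_interval
    windows = sorted(
        (pd.Timestamp(a), pd.Timestamp(b)) for a, b in eligible_windows
    )
    for (a1, b1), (a2, _) in zip(windows, windows[1:]):
        if a2 < b1:
            raise ValueError("eligible windows overlap")

    periods: list[ControlPeriod] = []
    t = log.frame["timestamp"]
    for start, end in windows:
        sub = log.frame[(t >= start) & (t <= end)]
        if sub.empty:
            continue
        gaps = sub["timestamp"].diff().dt.total_seconds().to_numpy()
        breaks = np.flatnonzero(gaps > gap_tolerance)
        for chunk in np.split(np.arange(len(sub)), breaks):
            if len(chunk) < 2:
                continue
            seg = sub.iloc[chunk]
            span = (
                seg["timestamp"].iloc[-1] - seg["timestamp"].iloc[0]
            ).total_seconds() / SECONDS_PER_DAY
            if span >= min_days:
                periods.append(ControlPeriod(log.patient_id, seg))
    return periods


# ---------------------------------------------------------------------------
# metadata tables


def read_events_csv(source) -> pd.DataFrame:
    """Read the event/annotation table (`patient_id,event_time,...`)."""
    events = pd.read_csv(source)
    events["event_time"] = pd.to_datetime(events["event_time"], format="ISO8601")
    for col in ("annotation_binary", "annotation_trinary"):
        if col not in events.columns:
            events[col] = None
    return events


def read_intervals_csv(source) -> pd.DataFrame:
    """Read the eligibility-interval table (`patient_id,start,end`)."""
    iv = pd.read_csv(source)
    iv["start"] = pd.to_datetime(iv["start"], format="ISO8601")
    iv["end"] = pd.to_datetime(iv["end"], format="ISO8601")
    return iv
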