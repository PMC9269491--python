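"""Activity-log I/O and day-period segmentation.

An activity log is a CSV file with one row per performed activity of daily
living (ADL): start timestamp, end timestamp, activity label. Rows are
grouped into :class:`DayLog` objects by the calendar date of the start time
and each day is segmented into the four periods of the day —

=========  =================
night      [00:00, 07:00)
morning    [07:00, 12:00)
afternoon  [12:00, 19:00)
evening    [19:00, 24:00)
=========  =================

Period membership is decided by the *start* time of a record; a record that
crosses a period boundary (e.g. a night's sleep ending mid-morning) is kept
whole and belongs to the period in which it started. Timestamps are
truncated to minute precision, so durations are integer minutes.
"""

from __future__ import annotations

import csv
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "PERIODS",
    "ActivityRecord",
    "DayLog",
    "PeriodSequence",
    "LogParseError",
    "LogValidationError",
    "period_of",
    "read_activity_log",
    "write_activity_log",
    "split_day",
    "split_days",
    "days_to_json",
]

#: Canonical period order (also the within-day concatenation order).
PERIODS: tuple[str, ...] = ("night", "morning", "afternoon", "evening")

# Half-open period windows in minutes from midnight; exhaustive over the day.
_PERIOD_BOUNDS: dict[str, tuple[int, int]] = {
    "night": (0, 7 * 60),
    "morning": (7 * 60, 12 * 60),
    "afternoon": (12 * 60, 19 * 60),
    "evening": (19 * 60, 24 * 60),
}


class LogParseError(ValueError):
    """A line of the activity file could not be parsed."""


class LogValidationError(ValueError):
    """A parsed record violates an invariant (e.g. end <= start)."""


def period_of(t: datetime.time) -> str:
    """Return the day period a time-of-day falls in (half-open windows)."""
    minutes = t.hour * 60 + t.minute
    for period, (lo, hi) in _PERIOD_BOUNDS.items():
        if lo <= minutes < hi:
            return period
    raise AssertionError("unreachable: periods partition the day")


@dataclass(frozen=True)
class ActivityRecord:
    """One performed activity: label plus start/end timestamps.

    Timestamps carry minute precision; ``duration`` is derived as
    ``end - start`` in whole minutes and is always positive.
    """

    activity_label: str
    start_time: datetime.datetime
    end_time: datetime.datetime

    def __post_init__(self) -> None:
        if not self.activity_label:
            raise LogValidationError("activity label must be non-empty")
        object.__setattr__(self, "start_time", _truncate(self.start_time))
        object.__setattr__(self, "end_time", _truncate(self.end_time))
        if self.end_time <= self.start_time:
            raise LogValidationError(
                f"end time {self.end_time} not after start time {self.start_time} "
                f"for activity {self.activity_label!r}"
            )

    @property
    def duration(self) -> int:
        """Duration in minutes."""
        return int((self.end_time - self.start_time).total_seconds() // 60)

    @property
    def day_id(self) -> datetime.date:
        """Calendar date of the start time (midnight-spanning records
        belong to the date they started on)."""
        return self.start_time.date()

    @property
    def start_minute(self) -> int:
        """Start time as minutes from that day's midnight."""
        return self.start_time.hour * 60 + self.start_time.minute

    @property
    def end_minute(self) -> int:
        """End expressed as minutes from the *start* day's midnight; may
        exceed 1440 for midnight-spanning records."""
        return self.start_minute + self.duration

    @property
    def period(self) -> str:
        return period_of(self.start_time.time())


@dataclass
class DayLog:
    """All activities of one calendar day, sorted by start time."""

    day_id: datetime.date
    records: list[ActivityRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.day_id != self.day_id:
                raise LogValidationError(
                    f"record starting {rec.start_time} does not belong to day {self.day_id}"
                )
        self.records = sorted(self.records, key=lambda r: (r.start_time, r.activity_label))


@dataclass
class PeriodSequence:
    """The ordered activity labels (with durations) of one day-period."""

    day_id: datetime.date
    period: str
    labels: list[str] = field(default_factory=list)
    durations: list[int] = field(default_factory=list)
    records: list[ActivityRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.labels)


def _truncate(ts: datetime.datetime) -> datetime.datetime:
    return ts.replace(second=0, microsecond=0)


def _parse_timestamp(text: str, lineno: int) -> datetime.datetime:
    try:
        return datetime.datetime.fromisoformat(text.strip())
    except ValueError as exc:
        raise LogParseError(f"line {lineno}: malformed timestamp {text!r}") from exc


_HEADER = ("start_time", "end_time", "activity")


def read_activity_log(path: str | Path, dialect: str = "auto") -> list[DayLog]:
    """Read an activity-log CSV into per-day logs.

    Parameters
    ----------
    path
        CSV file with columns ``start_time,end_time,activity`` (ISO-8601
        timestamps). ``dialect`` is one of ``"auto"`` (header detected),
        ``"header"`` or ``"headerless"``.

    Returns
    -------
    list of :class:`DayLog`, sorted by date, each internally sorted by
    start time. Durations are computed in whole minutes.
    """
    if dialect not in ("auto", "header", "headerless"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    rows = [(i + 1, row) for i, row in enumerate(rows) if row and any(c.strip() for c in row)]
    if not rows:
        return []
    start = 0
    if dialect == "header" or (
        dialect == "auto" and [c.strip() for c in rows[0][1]] == list(_HEADER)
    ):
        start = 1
    records: list[ActivityRecord] = []
    for lineno, row in rows[start:]:
        if len(row) != 3:
            raise LogParseError(f"line {lineno}: expected 3 fields, got {len(row)}")
        t0 = _parse_timestamp(row[0], lineno)
        t1 = _parse_timestamp(row[1], lineno)
        label = row[2].strip()
        try:
            records.append(ActivityRecord(label, t0, t1))
        except LogValidationError as exc:
            raise LogValidationError(f"line {lineno}: {exc}") from exc
    by_day: dict[datetime.date, list[ActivityRecord]] = {}
    for rec in records:
        by_day.setdefault(rec.day_id, []).append(rec)
    return [DayLog(day, recs) for day, recs in sorted(by_day.items())]


def write_activity_log(days: Sequence[DayLog], path: str | Path) -> None:
    """Write day logs back to the CSV dialect of :func:`read_activity_log`.

    Round-trips bit-identically through :func:`read_activity_log`; days
    holding no records are omitted from the file.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_HEADER)
        for day in sorted(days, key=lambda d: d.day_id):
            for rec in day.records:
                writer.writerow(
                    (
                        rec.start_time.isoformat(timespec="seconds"),
                        rec.end_time.isoformat(timespec="seconds"),
                        rec.activity_label,
                    )
                )


def split_day(day: DayLog, split_boundary_crossers: bool = False) -> dict[str, PeriodSequence]:
    """Segment a day into the four period sequences.

    Every record is assigned to exactly one period by its start time;
    periods without records map to empty sequences. With
    ``split_boundary_crossers`` a record that runs past its period's end is
    chopped at each boundary and its parts assigned to their own periods
    (off by default: a night's sleep that ends mid-morning stays one
    night-period entry with its full duration).
    """
    out = {p: PeriodSequence(day.day_id, p) for p in PERIODS}
    for rec in day.records:
        parts = _split_parts(rec) if split_boundary_crossers else [(rec.period, rec)]
        for period, part in parts:
            seq = out[period]
            seq.labels.append(part.activity_label)
            seq.durations.append(part.duration)
            seq.records.append(part)
    return out


def _split_parts(rec: ActivityRecord) -> list[tuple[str, ActivityRecord]]:
    parts: list[tuple[str, ActivityRecord]] = []
    cursor = rec.start_time
    while cursor < rec.end_time:
        period = period_of(cursor.time())
        hi = _PERIOD_BOUNDS[period][1]
        boundary = cursor.replace(hour=0, minute=0) + datetime.timedelta(minutes=hi)
        stop = min(rec.end_time, boundary)
        parts.append((period, ActivityRecord(rec.activity_label, cursor, stop)))
        cursor = stop
    return parts


def split_days(
    days: Iterable[DayLog], split_boundary_crossers: bool = False
) -> dict[datetime.date, dict[str, PeriodSequence]]:
    """Segment every day; returns ``{day_id: {period: PeriodSequence}}``."""
    return {d.day_id: split_day(d, split_boundary_crossers) for d in days}


def days_to_json(days: Sequence[DayLog]) -> str:
    """JSON export of day logs (debugging aid)."""
    payload = [
        {
            "day": day.day_id.isoformat(),
            "records": [
                {
                    "activity": r.activity_label,
                    "start": r.start_time.isoformat(timespec="seconds"),
                    "end": r.end_time.isoformat(timespec="seconds"),
                    "duration_min": r.duration,
                    "period": r.period,
                }
                for r in day.records
            ],
        }
        for day in days
    ]
    return json.dumps(payload, indent=2)


def vocabulary(days: Iterable[DayLog]) -> list[str]:
    """Distinct activity labels in order of first appearance."""
    seen: dict[str, None] = {}
    for day in sorted(days, key=lambda d: d.day_id):
        for rec in day.records:
            seen.setdefault(rec.activity_label, None)
    return list(seen)
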