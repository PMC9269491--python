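"""Flexible daily-routine assembly and the history-coverage metric.

A daily routine is four per-period sub-routines. Each routine entry holds
one activity of one period with

* an *interval*: earliest start and latest end over the surviving days,
* a *timespan*: mean duration over its occurrences on surviving days,
* a *required* flag: mandatory (performed on nearly every surviving day),
  optional (performed sometimes), or excluded from the routine,
* an optional *alternative group* ("<>"): optional entries that occupy
  overlapping intervals but never co-occur on the same day-period are
  mutually exclusive ways of filling that slot,
* a *duration category* (instant / short / medium / long), and
* possibly several *variants* of the same activity when its timespans fall
  in distinct duration clusters (e.g. a night's sleep of ~8 h vs ~9 h).

The *coverage* metric scores the whole monitoring history against the
routine: a day is covered when it contains at least one frequent pattern,
at least half of its activity instances belong to frequent patterns of
their period, and every activity matched by the routine stays within its
timespan band and overlaps its routine interval (period-matched).
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .gapbide import Pattern
from .day_filtering import contains_contiguous
from .log_io import PERIODS, PeriodSequence

__all__ = [
    "RoutineEntry",
    "DailyRoutine",
    "CoverageReport",
    "RoutineError",
    "routine_timespan",
    "routine_interval",
    "classify_required",
    "detect_alternatives",
    "duration_category",
    "build_routine",
    "coverage",
]

DaySegments = Mapping[datetime.date, Mapping[str, PeriodSequence]]

#: duration-category boundaries in minutes: instant < 5 <= short < 30 <=
#: medium < 120 <= long (right-closed left bucket: 30 min is medium)
DEFAULT_CATEGORY_BOUNDS = (5, 30, 120)


class RoutineError(ValueError):
    """Raised when no routine can be assembled (e.g. no surviving days)."""


@dataclass
class RoutineEntry:
    """One activity slot of a period sub-routine."""

    activity: str
    period: str
    t_start: int  # minutes from midnight
    t_end: int  # minutes from midnight of the start day; may exceed 1440
    timespan: float  # minutes
    required: str  # "mandatory" | "optional"
    alt_group: str | None = None
    duration_category: str = "short"
    n_days: int = 0  # surviving days on which the activity occurred
    presence_fraction: float = 0.0
    variant: int | None = None  # duration-cluster variant index, if any

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise RoutineError(
                f"entry {self.activity}/{self.period}: t_end must exceed t_start"
            )
        if self.timespan <= 0:
            raise RoutineError(f"entry {self.activity}: timespan must be positive")

    def interval_str(self) -> str:
        return f"{_fmt(self.t_start)}-{_fmt(self.t_end)}"


def _fmt(minutes: int) -> str:
    h, m = divmod(minutes % 1440, 60)
    return f"{h:02d}:{m:02d}"


@dataclass
class DailyRoutine:
    """Four per-period sub-routines plus the mined patterns behind them."""

    sub_routines: dict[str, list[RoutineEntry]] = field(
        default_factory=lambda: {p: [] for p in PERIODS}
    )
    patterns_by_period: dict[str, list[tuple[str, ...]]] = field(default_factory=dict)
    alpha: float = 0.2
    n_source_days: int = 0

    def entries(self) -> list[RoutineEntry]:
        return [e for p in PERIODS for e in self.sub_routines[p]]

    def to_records(self) -> list[dict]:
        """Fig-12-shaped table rows (CSV/JSON export)."""
        return [
            {
                "period": e.period,
                "activity": e.activity,
                "t_start": _fmt(e.t_start),
                "t_end": _fmt(e.t_end),
                "timespan_min": round(e.timespan, 1),
                "required": e.required == "mandatory",
                "alt_group": e.alt_group or "",
                "category": e.duration_category,
            }
            for e in self.entries()
        ]


@dataclass
class CoverageReport:
    """Share of the monitoring history compatible with the routine."""

    covered_days: int
    total_days: int
    per_day: dict[datetime.date, dict] = field(default_factory=dict)

    @property
    def coverage(self) -> float:
        """Coverage in percent."""
        return 100.0 * self.covered_days / self.total_days if self.total_days else 0.0


def _occurrences(
    activity: str, period: str, day_ids: Sequence[datetime.date], segments: DaySegments
):
    for day_id in sorted(day_ids):
        seq = segments[day_id].get(period)
        if seq is None:
            continue
        for rec in seq.records:
            if rec.activity_label == activity:
                yield rec


def routine_timespan(
    activity: str,
    period: str,
    day_ids: Sequence[datetime.date],
    segments: DaySegments,
) -> float:
    """Mean duration (minutes) of the activity's occurrences in that
    period across the given days."""
    durations = [r.duration for r in _occurrences(activity, period, day_ids, segments)]
    if not durations:
        raise RoutineError(f"{activity!r} never occurs in {period} on the given days")
    return float(np.mean(durations))


def routine_interval(
    activity: str,
    period: str,
    day_ids: Sequence[datetime.date],
    segments: DaySegments,
) -> tuple[int, int]:
    """Earliest start and latest end (minutes from midnight) of the
    activity in that period across the given days."""
    recs = list(_occurrences(activity, period, day_ids, segments))
    if not recs:
        raise RoutineError(f"{activity!r} never occurs in {period} on the given days")
    return min(r.start_minute for r in recs), max(r.end_minute for r in recs)


def classify_required(
    presence_fraction: float,
    mandatory_frac: float = 0.9,
    optional_frac: float = 0.3,
) -> str:
    """Mandatory / optional / excluded by presence across surviving days."""
    if presence_fraction >= mandatory_frac:
        return "mandatory"
    if presence_fraction >= optional_frac:
        return "optional"
    return "excluded"


def duration_category(
    timespan: float, bounds: tuple[int, int, int] = DEFAULT_CATEGORY_BOUNDS
) -> str:
    """Bucket a timespan: instant < b0 <= short < b1 <= medium < b2 <= long."""
    b0, b1, b2 = bounds
    if timespan < b0:
        return "instant"
    if timespan < b1:
        return "short"
    if timespan < b2:
        return "medium"
    return "long"


def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def detect_alternatives(
    entries: Sequence[RoutineEntry],
    presence: Mapping[tuple[str, str], set[datetime.date]],
    overlap_frac: float = 0.5,
) -> None:
    """Assign alternative-group tags ("<>") in place.

    Two *optional* entries of the same period are alternatives when their
    intervals overlap by at least ``overlap_frac`` of the shorter interval
    and they never co-occur on the same day-period. Mandatory entries are
    never grouped. Groups are the connected components of this relation.
    """
    by_period: dict[str, list[RoutineEntry]] = {}
    for e in entries:
        by_period.setdefault(e.period, []).append(e)
    for period, group in by_period.items():
        optional = [e for e in group if e.required == "optional"]
        parent = list(range(len(optional)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(optional)):
            for j in range(i + 1, len(optional)):
                a, b = optional[i], optional[j]
                if a.activity == b.activity:
                    continue
                shorter = min(a.t_end - a.t_start, b.t_end - b.t_start)
                ov = _overlap(a.t_start, a.t_end, b.t_start, b.t_end)
                if shorter <= 0 or ov < overlap_frac * shorter:
                    continue
                if presence.get((a.activity, period), set()) & presence.get(
                    (b.activity, period), set()
                ):
                    continue  # co-occur at least once: not alternatives
                parent[find(i)] = find(j)
        roots: dict[int, list[RoutineEntry]] = {}
        for i, e in enumerate(optional):
            roots.setdefault(find(i), []).append(e)
        counter = 0
        for members in roots.values():
            if len(members) > 1:
                counter += 1
                for e in members:
                    e.alt_group = f"{period}-alt{counter}"


def build_routine(
    surviving_day_ids: Sequence[datetime.date],
    segments: DaySegments,
    patterns_by_period: Mapping[str, Sequence[Pattern]] | None = None,
    variant_labels: Mapping[tuple[datetime.date, str], int] | None = None,
    alpha: float = 0.2,
    mandatory_frac: float = 0.9,
    optional_frac: float = 0.3,
    overlap_frac: float = 0.5,
    category_bounds: tuple[int, int, int] = DEFAULT_CATEGORY_BOUNDS,
) -> DailyRoutine:
    """Assemble the flexible routine from the surviving days.

    ``variant_labels`` optionally maps each (day, period) to a duration
    cluster; an activity whose per-cluster mean timespans differ by more
    than ``alpha`` times the smaller mean yields one entry per such
    cluster group (the routine's alternative duration variants), otherwise
    the clusters are merged into a single entry.
    """
    days = sorted(set(surviving_day_ids))
    if not days:
        raise RoutineError("no routine days survive filtering")
    routine = DailyRoutine(alpha=alpha, n_source_days=len(days))
    if patterns_by_period:
        routine.patterns_by_period = {
            p: [tuple(pat.labels) for pat in pats]
            for p, pats in patterns_by_period.items()
        }
    presence: dict[tuple[str, str], set[datetime.date]] = {}
    for period in PERIODS:
        activities: dict[str, None] = {}
        for day_id in days:
            seq = segments[day_id].get(period)
            if seq is None:
                continue
            for label in seq.labels:
                activities.setdefault(label, None)
                presence.setdefault((label, period), set()).add(day_id)
        entries: list[RoutineEntry] = []
        for activity in activities:
            day_pres = presence[(activity, period)]
            frac = len(day_pres) / len(days)
            required = classify_required(frac, mandatory_frac, optional_frac)
            if required == "excluded":
                continue
            groups = _variant_groups(
                activity, period, sorted(day_pres), segments, variant_labels, alpha
            )
            for idx, group_days in enumerate(groups):
                ts = routine_timespan(activity, period, group_days, segments)
                t0, t1 = routine_interval(activity, period, group_days, segments)
                entries.append(
                    RoutineEntry(
                        activity=activity,
                        period=period,
                        t_start=t0,
                        t_end=t1,
                        timespan=ts,
                        required=required,
                        duration_category=duration_category(ts, category_bounds),
                        n_days=len(group_days),
                        presence_fraction=frac,
                        variant=idx if len(groups) > 1 else None,
                    )
                )
        entries.sort(key=lambda e: (e.t_start, e.t_end, e.activity))
        routine.sub_routines[period] = entries
    detect_alternatives(routine.entries(), presence, overlap_frac)
    return routine


def _variant_groups(
    activity: str,
    period: str,
    day_ids: Sequence[datetime.date],
    segments: DaySegments,
    variant_labels: Mapping[tuple[datetime.date, str], int] | None,
    alpha: float,
) -> list[list[datetime.date]]:
    """Partition an activity's days into duration-variant groups.

    Days are first grouped by cluster label; groups whose mean timespans
    are within ``alpha`` of each other are merged (they are the same
    variant up to jitter).
    """
    if variant_labels is None:
        return [list(day_ids)]
    by_cluster: dict[int, list[datetime.date]] = {}
    for day_id in day_ids:
        label = variant_labels.get((day_id, period), -1)
        by_cluster.setdefault(label, []).append(day_id)
    groups = [
        (routine_timespan(activity, period, g, segments), g)
        for g in by_cluster.values()
    ]
    groups.sort(key=lambda t: t[0])
    merged: list[tuple[float, list[datetime.date]]] = []
    for ts, g in groups:
        if merged and ts - merged[-1][0] <= alpha * merged[-1][0]:
            prev_ts, prev_g = merged[-1]
            new_g = prev_g + g
            merged[-1] = (routine_timespan(activity, period, new_g, segments), new_g)
        else:
            merged.append((ts, g))
    return [g for _, g in merged]


def coverage(
    routine: DailyRoutine,
    segments: DaySegments,
    min_pattern_fraction: float = 0.5,
) -> CoverageReport:
    """Score every day of the history against the routine.

    A day is covered when

    a. at least one period sequence contains a frequent pattern of its
       period as a contiguous substring,
    b. at least ``min_pattern_fraction`` of the day's activity instances
       carry labels that appear in some frequent pattern of their period,
    c. every activity instance the routine knows (label present in the
       period's sub-routine) matches some entry of that label: duration
       inside the entry's ``timespan * (1 +/- alpha)`` band and interval
       overlapping the entry's interval.
    """
    report = CoverageReport(covered_days=0, total_days=0)
    pattern_labels = {
        p: {lab for pat in routine.patterns_by_period.get(p, []) for lab in pat}
        for p in PERIODS
    }
    routine_acts = {
        p: {e.activity for e in routine.sub_routines[p]} for p in PERIODS
    }
    for day_id in sorted(segments):
        verdict: dict = {"failed": []}
        has_pattern = False
        n_instances = 0
        n_frequent = 0
        timespan_ok = True
        bad_activities: list[str] = []
        for period in PERIODS:
            seq = segments[day_id].get(period)
            if seq is None or not len(seq):
                continue
            if any(
                contains_contiguous(seq.labels, pat)
                for pat in routine.patterns_by_period.get(period, [])
            ):
                has_pattern = True
            for rec in seq.records:
                n_instances += 1
                if rec.activity_label in pattern_labels[period]:
                    n_frequent += 1
                if rec.activity_label in routine_acts[period]:
                    entries = [
                        e
                        for e in routine.sub_routines[period]
                        if e.activity == rec.activity_label
                    ]
                    if not any(_matches(rec, e, routine.alpha) for e in entries):
                        timespan_ok = False
                        bad_activities.append(f"{period}:{rec.activity_label}")
        if not has_pattern:
            verdict["failed"].append("no_routine_pattern")
        frequent_frac = n_frequent / n_instances if n_instances else 0.0
        if frequent_frac < min_pattern_fraction:
            verdict["failed"].append("too_few_frequent_activities")
        if not timespan_ok:
            verdict["failed"].append("timespan_or_interval_mismatch")
            verdict["mismatched"] = bad_activities
        verdict["frequent_fraction"] = round(frequent_frac, 3)
        verdict["covered"] = not verdict["failed"]
        report.per_day[day_id] = verdict
        report.total_days += 1
        if verdict["covered"]:
            report.covered_days += 1
    return report


def _matches(rec, entry: RoutineEntry, alpha: float) -> bool:
    low, high = entry.timespan * (1 - alpha), entry.timespan * (1 + alpha)
    if not (low <= rec.duration <= high):
        return False
    return _overlap(rec.start_minute, rec.end_minute, entry.t_start, entry.t_end) > 0
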