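"""Candidate routine-day selection.

Two filtering stages pick out the days that can plausibly represent a
routine:

1. *Pattern containment*: a day is retained when, in at least
   ``min_periods`` (default 3) of its four periods, the period's activity
   sequence contains at least one mined pattern of that period as a
   contiguous substring — same order, no interspersed activities.
2. *Length-frequency threshold*: over the retained days, each period's
   distinct sequence lengths are tabulated. With ``n`` distinct lengths
   each length's nominal share is ``1/n``; a sequence passes when the
   relative frequency of its length is at least half that nominal share
   (five distinct lengths -> nominal 20 %, threshold 10 %). A day is kept
   when at least ``min_periods`` of its periods pass. This removes days
   built from atypically short/long sequences even when they contain
   frequent patterns.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .gapbide import Pattern
from .log_io import PERIODS, PeriodSequence

__all__ = [
    "LengthFrequencyTable",
    "FilteredDaySet",
    "contains_contiguous",
    "days_with_patterns",
    "build_length_tables",
    "length_threshold",
    "filter_by_length",
]

DaySegments = Mapping[datetime.date, Mapping[str, PeriodSequence]]


@dataclass
class LengthFrequencyTable:
    """Per-period table ``{sequence length: number of sequences}``."""

    period: str
    entries: dict[int, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.entries.values())

    def relative_frequency(self, length: int) -> float:
        return self.entries.get(length, 0) / self.total if self.total else 0.0


@dataclass
class FilteredDaySet:
    """Retained days plus a per-day record of why they were kept/dropped."""

    day_ids: set[datetime.date] = field(default_factory=set)
    provenance: dict[datetime.date, dict] = field(default_factory=dict)

    def __contains__(self, day_id: datetime.date) -> bool:
        return day_id in self.day_ids

    def __len__(self) -> int:
        return len(self.day_ids)


def contains_contiguous(labels: Sequence[str], pattern: Sequence[str]) -> bool:
    """True iff ``pattern`` occurs in ``labels`` as a contiguous substring."""
    n, m = len(labels), len(pattern)
    if m == 0 or m > n:
        return False
    return any(list(labels[i : i + m]) == list(pattern) for i in range(n - m + 1))


def days_with_patterns(
    segments: DaySegments,
    patterns_by_period: Mapping[str, Sequence[Pattern]],
    min_periods: int = 3,
    top_days: int | None = None,
) -> FilteredDaySet:
    """Stage 1: keep days whose sequences contain mined patterns in at
    least ``min_periods`` periods.

    Containment is contiguous and order-preserving regardless of the gap
    constraint used during mining. With ``top_days`` only the N days with
    the most matched patterns (ties broken by date) are kept among those
    passing the period threshold.
    """
    if not 1 <= min_periods <= len(PERIODS):
        raise ValueError(f"min_periods must be in [1, {len(PERIODS)}]")
    result = FilteredDaySet()
    scored: list[tuple[int, datetime.date]] = []
    for day_id, periods in segments.items():
        matched: dict[str, list[tuple[str, ...]]] = {}
        n_matches = 0
        for period in PERIODS:
            seq = periods.get(period)
            if seq is None or not seq.labels:
                continue
            hits = [
                p.labels
                for p in patterns_by_period.get(period, [])
                if contains_contiguous(seq.labels, p.labels)
            ]
            if hits:
                matched[period] = hits
                n_matches += len(hits)
        if len(matched) >= min_periods:
            scored.append((n_matches, day_id))
            result.provenance[day_id] = {
                "matched_periods": sorted(matched),
                "n_pattern_matches": n_matches,
            }
    scored.sort(key=lambda t: (-t[0], t[1]))
    keep = scored if top_days is None else scored[:top_days]
    result.day_ids = {day for _, day in keep}
    result.provenance = {d: result.provenance[d] for d in result.day_ids}
    return result


def build_length_tables(
    day_set: FilteredDaySet, segments: DaySegments
) -> dict[str, LengthFrequencyTable]:
    """Length-frequency tables per period over the stage-1 survivors.

    Empty period sequences contribute no length entry.
    """
    tables = {p: LengthFrequencyTable(p) for p in PERIODS}
    for day_id in sorted(day_set.day_ids):
        for period in PERIODS:
            seq = segments[day_id].get(period)
            if seq is not None and len(seq):
                table = tables[period].entries
                table[len(seq)] = table.get(len(seq), 0) + 1
    return tables


def length_threshold(table: LengthFrequencyTable) -> float:
    """Minimum relative frequency a sequence length must reach.

    Each of the ``n`` distinct lengths nominally holds a ``1/n`` share of
    the period's sequences; the acceptance threshold is half of that.
    """
    n = len(table.entries)
    if n == 0:
        raise ValueError(f"length table for period {table.period!r} is empty")
    return (1.0 / n) / 2.0


def filter_by_length(
    day_set: FilteredDaySet,
    tables: Mapping[str, LengthFrequencyTable],
    segments: DaySegments,
    min_periods: int = 3,
) -> FilteredDaySet:
    """Stage 2: keep days whose sequence lengths are common enough in at
    least ``min_periods`` periods (ties at the threshold pass)."""
    result = FilteredDaySet()
    for day_id in sorted(day_set.day_ids):
        passing: list[str] = []
        failing: list[str] = []
        for period in PERIODS:
            seq = segments[day_id].get(period)
            if seq is None or not len(seq):
                failing.append(period)
                continue
            table = tables[period]
            if not table.entries:
                failing.append(period)
                continue
            if table.relative_frequency(len(seq)) >= length_threshold(table):
                passing.append(period)
            else:
                failing.append(period)
        if len(passing) >= min_periods:
            result.day_ids.add(day_id)
            result.provenance[day_id] = dict(
                day_set.provenance.get(day_id, {}), length_pass=passing
            )
        else:
            # rejected days keep a trace of the periods that failed
            result.provenance[day_id] = dict(
                day_set.provenance.get(day_id, {}),
                length_pass=passing,
                length_fail=failing,
                rejected=True,
            )
    return result
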