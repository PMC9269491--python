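"""Synthetic activity-log generation with a planted flexible routine.

The generator emulates the multi-week log of a single monitored person:
each day repeats a per-period schedule in which mandatory activities are
always performed, optional activities are dropped with a stated
probability, exactly one member of each alternative group is chosen, and
durations/start times are jittered around period-specific means (truncated
normal, at least one minute). A stated share of days is replaced by *noise
days* — a random sequence of random activities with arbitrary durations —
mimicking the anomalous days a routine should not cover.

What this emulates: the repetition, optionality, alternatives and duration
jitter of real ADL schedules. What it does not: sensor noise,
mis-classified activities, weekday/weekend structure, or gradual drift —
conclusions from passing tests are about the mining/clustering machinery,
not about classifier robustness.

Everything is deterministic given the template seed.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .log_io import ActivityRecord, DayLog

__all__ = [
    "ActivitySpec",
    "RoutineTemplate",
    "GenerationError",
    "generate_log",
    "default_template",
    "ground_truth_compare",
]


class GenerationError(ValueError):
    """The template's schedule cannot fit in a day."""


@dataclass(frozen=True)
class ActivitySpec:
    """One scheduled activity of the planted routine."""

    label: str
    period: str
    start_minute: int  # nominal start, minutes from midnight
    mean_duration: float  # minutes
    duration_sd: float = 0.0
    start_sd: float = 0.0
    presence_prob: float = 1.0  # 1.0 = mandatory
    alt_group: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.presence_prob <= 1:
            raise ValueError("presence probability must be in (0, 1]")
        if self.duration_sd < 0 or self.start_sd < 0:
            raise ValueError("jitter standard deviations must be >= 0")


@dataclass
class RoutineTemplate:
    """The ground-truth schedule a synthetic log is drawn from."""

    specs: list[ActivitySpec]
    n_days: int = 30
    noise_day_probability: float = 0.0
    seed: int = 0
    start_date: datetime.date = datetime.date(2021, 3, 1)

    @property
    def vocabulary(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.specs:
            seen.setdefault(s.label, None)
        return list(seen)

    @property
    def n_noise_days(self) -> int:
        # fixed count so the planted contamination level is exact
        return round(self.noise_day_probability * self.n_days)


def default_template(
    n_days: int = 30, noise_day_probability: float = 0.0, seed: int = 0
) -> RoutineTemplate:
    """A realistic single-person month: sleep through the night, hygiene
    and breakfast in the morning with a toileting-or-TV alternative slot,
    lunch / optional nap / TV in the afternoon, dinner and TV with an
    optional snack in the evening. Duration jitter is a few percent of
    each mean, start jitter ~10 min."""
    m = lambda h, mi=0: h * 60 + mi
    specs = [
        ActivitySpec("Toileting", "night", m(0, 30), 8, 0.5, 5),
        ActivitySpec("Sleeping", "night", m(1, 15), 480, 15, 10),
        ActivitySpec("Personal hygiene", "morning", m(9, 40), 15, 0.5, 8),
        ActivitySpec("Breakfast", "morning", m(10, 5), 30, 1, 8),
        ActivitySpec("Toileting", "morning", m(11, 30), 10, 0.5, 5,
                     presence_prob=0.5, alt_group="late-morning"),
        ActivitySpec("Spare time/TV", "morning", m(11, 30), 70, 2, 5,
                     presence_prob=0.5, alt_group="late-morning"),
        ActivitySpec("Lunch", "afternoon", m(13, 0), 40, 1.5, 10),
        ActivitySpec("Nap", "afternoon", m(14, 30), 60, 2, 10, presence_prob=0.5),
        ActivitySpec("Spare time/TV", "afternoon", m(16, 0), 120, 4, 10),
        ActivitySpec("Dinner", "evening", m(19, 30), 35, 1, 8),
        ActivitySpec("Spare time/TV", "evening", m(20, 30), 90, 3, 8),
        ActivitySpec("Snack", "evening", m(22, 30), 25, 1, 5, presence_prob=0.5),
    ]
    return RoutineTemplate(
        specs=specs,
        n_days=n_days,
        noise_day_probability=noise_day_probability,
        seed=seed,
    )


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> int:
    """Integer minutes, at least 1."""
    return max(1, int(round(rng.normal(mean, sd)))) if sd > 0 else max(1, round(mean))


def generate_log(template: RoutineTemplate) -> tuple[list[DayLog], dict]:
    """Draw a synthetic activity log plus its ground truth.

    Returns the day logs (sorted) and a ground-truth dict with the noise
    days, per-day chosen alternatives and emitted activities.
    """
    rng = np.random.default_rng(template.seed)
    n_noise = template.n_noise_days
    noise_idx = set(
        rng.choice(template.n_days, size=n_noise, replace=False).tolist()
    ) if n_noise else set()
    alt_groups: dict[str, list[ActivitySpec]] = {}
    for s in template.specs:
        if s.alt_group:
            alt_groups.setdefault(s.alt_group, []).append(s)
    days: list[DayLog] = []
    truth: dict = {
        "noise_days": [],
        "clean_days": [],
        "per_day": {},
        "template_seed": template.seed,
    }
    vocab = template.vocabulary
    for i in range(template.n_days):
        day = template.start_date + datetime.timedelta(days=i)
        midnight = datetime.datetime.combine(day, datetime.time())
        if i in noise_idx:
            records = _noise_day(rng, midnight, vocab)
            truth["noise_days"].append(day.isoformat())
            truth["per_day"][day.isoformat()] = {"noise": True}
        else:
            records, chosen = _clean_day(rng, midnight, template, alt_groups)
            truth["clean_days"].append(day.isoformat())
            truth["per_day"][day.isoformat()] = {
                "noise": False,
                "chosen_alternatives": chosen,
                "activities": [r.activity_label for r in records],
            }
        days.append(DayLog(day, records))
    return days, truth


def _clean_day(rng, midnight, template, alt_groups) -> tuple[list[ActivityRecord], dict]:
    chosen_alt: dict[str, str] = {
        g: members[rng.integers(len(members))].label
        for g, members in alt_groups.items()
    }
    records: list[ActivityRecord] = []
    prev_end = 0
    for spec in template.specs:
        if spec.alt_group:
            if chosen_alt[spec.alt_group] != spec.label:
                continue
        elif spec.presence_prob < 1 and rng.random() >= spec.presence_prob:
            continue
        start = spec.start_minute
        if spec.start_sd > 0:
            start = int(round(rng.normal(spec.start_minute, spec.start_sd)))
        start = max(start, prev_end)  # forward-shift to preserve order
        duration = _truncated_normal(rng, spec.mean_duration, spec.duration_sd)
        if start >= 1440:
            raise GenerationError(
                f"schedule overruns the day at {spec.label!r} (start {start} min)"
            )
        records.append(
            ActivityRecord(
                spec.label,
                midnight + datetime.timedelta(minutes=start),
                midnight + datetime.timedelta(minutes=start + duration),
            )
        )
        prev_end = start + duration
    return records, chosen_alt


def _noise_day(rng, midnight, vocab: Sequence[str]) -> list[ActivityRecord]:
    """A random permutation of random activities with arbitrary timing."""
    n = int(rng.integers(5, 11))
    t = int(rng.integers(0, 120))
    records: list[ActivityRecord] = []
    for _ in range(n):
        if t >= 1380:
            break
        label = vocab[rng.integers(len(vocab))]
        duration = int(rng.integers(10, 181))
        records.append(
            ActivityRecord(
                label,
                midnight + datetime.timedelta(minutes=t),
                midnight + datetime.timedelta(minutes=t + duration),
            )
        )
        t += duration + int(rng.integers(5, 121))
    return records


def ground_truth_compare(routine, template: RoutineTemplate) -> dict:
    """Compare a mined routine against the planted template.

    Per (activity, period) spec: whether it was recovered, the absolute
    error of the pooled (presence-weighted across variants) mean timespan
    vs the template mean, whether the routine interval contains the
    nominal start, and whether the required flag agrees (mandatory iff
    presence probability is 1 for non-alternative specs).
    """
    report: dict = {"activities": {}, "all_mandatory_recovered": True}
    for spec in template.specs:
        key = f"{spec.period}:{spec.label}"
        entries = [
            e for e in routine.sub_routines.get(spec.period, [])
            if e.activity == spec.label
        ]
        if not entries:
            report["activities"][key] = {"recovered": False}
            if spec.presence_prob == 1:
                report["all_mandatory_recovered"] = False
            continue
        total_days = sum(e.n_days for e in entries)
        pooled = sum(e.timespan * e.n_days for e in entries) / total_days
        t0 = min(e.t_start for e in entries)
        t1 = max(e.t_end for e in entries)
        mandatory = all(e.required == "mandatory" for e in entries)
        report["activities"][key] = {
            "recovered": True,
            "timespan_error_min": abs(pooled - spec.mean_duration),
            "within_2sd": abs(pooled - spec.mean_duration) <= max(2 * spec.duration_sd, 1.0),
            "interval_contains_nominal_start": t0 <= spec.start_minute <= t1,
            "required_flag_agrees": mandatory == (spec.presence_prob == 1 and spec.alt_group is None),
            "n_variants": len(entries),
        }
    return report
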