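"""End-to-end routine-discovery pipeline.

Stages: segment days into periods -> mine closed frequent patterns per
period -> filter candidate routine days (pattern containment, then
length-frequency) -> collaboratively cluster timespan vectors and filter
(centroid-ratio via K-Means/DTW, representative clusters via agglomerative
Manhattan) -> combine the two day sets -> assemble the flexible routine ->
score coverage over the full monitoring history.

`run_pipeline` is deterministic given the input log and config, and can
write each stage's JSON artifact plus a run manifest.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__
from .clustering import (
    build_vectors,
    centroid_ratio_filter,
    combine,
    kmeans_dtw,
    representative_cluster_filter,
    select_k_agglomerative,
    select_k_kmeans,
)
from .day_filtering import (
    FilteredDaySet,
    build_length_tables,
    days_with_patterns,
    filter_by_length,
)
from .gapbide import GapConstraint, mine_per_period, patterns_to_json
from .log_io import PERIODS, DayLog, read_activity_log, split_days
from .routine import CoverageReport, DailyRoutine, RoutineError, build_routine, coverage

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "holdout_split"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline.

    ``min_support`` is the number of days a pattern must repeat on to be
    frequent (default 5, about one sixth of a month-long log); ``gap`` the
    Gap-BIDE gap constraint (default (0, 0): consecutive activities only);
    ``alpha`` the allowed relative timespan deviation around a cluster
    centroid / routine entry.
    """

    min_support: int = 5
    gap: tuple[int, int] = (0, 0)
    min_pattern_length: int = 1
    min_periods: int = 3
    alpha: float = 0.2
    k_range: tuple[int, int] | None = None  # default [2, n/2] per period
    combine_mode: str = "union"
    mandatory_frac: float = 0.9
    optional_frac: float = 0.3
    min_size_frac: float = 0.10
    overlap_frac: float = 0.5
    category_bounds: tuple[int, int, int] = (5, 30, 120)
    seed: int = 0
    train_frac: float = 1.0
    random_split: bool = False
    split_boundary_crossers: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("gap", "k_range", "category_bounds"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    routine: DailyRoutine
    coverage_all: CoverageReport
    coverage_train: CoverageReport
    coverage_eval: CoverageReport | None
    surviving: FilteredDaySet
    kmeans_days: FilteredDaySet
    agglomerative_days: FilteredDaySet
    artifacts: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def holdout_split(
    days: Sequence[DayLog],
    train_frac: float,
    seed: int = 0,
    random_split: bool = False,
) -> tuple[list[DayLog], list[DayLog]]:
    """Split days into train/eval portions.

    Chronological by default (routines should generalise forward in time);
    a seeded random split is available behind ``random_split``.
    """
    if not 0 < train_frac <= 1:
        raise ValueError("train_frac must be in (0, 1]")
    ordered = sorted(days, key=lambda d: d.day_id)
    n_train = max(1, round(train_frac * len(ordered)))
    if train_frac == 1.0:
        return list(ordered), []
    if random_split:
        rng = np.random.default_rng(seed)
        idx = rng.permutation(len(ordered))
        train = sorted((ordered[i] for i in idx[:n_train]), key=lambda d: d.day_id)
        hold = sorted((ordered[i] for i in idx[n_train:]), key=lambda d: d.day_id)
        return train, hold
    return ordered[:n_train], ordered[n_train:]


def run_pipeline(
    log: str | Path | Sequence[DayLog],
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full pipeline on an activity log (path or day list)."""
    config = config or PipelineConfig()
    days = (
        read_activity_log(log)
        if isinstance(log, (str, Path))
        else sorted(log, key=lambda d: d.day_id)
    )
    if not days:
        raise PipelineError("segmentation: the activity log holds no days")
    train_days, eval_days = holdout_split(
        days, config.train_frac, config.seed, config.random_split
    )
    segments = split_days(days, config.split_boundary_crossers)
    train_ids = [d.day_id for d in train_days]

    # -- mining ------------------------------------------------------------
    try:
        corpora = {
            period: {
                day_id: tuple(segments[day_id][period].labels)
                for day_id in train_ids
                if len(segments[day_id][period])
            }
            for period in PERIODS
        }
        patterns = mine_per_period(
            corpora,
            config.min_support,
            GapConstraint(*config.gap),
            config.min_pattern_length,
        )
    except Exception as exc:
        raise PipelineError(f"mining: {exc}") from exc

    # -- day filtering -----------------------------------------------------
    try:
        train_segments = {d: segments[d] for d in train_ids}
        stage1 = days_with_patterns(train_segments, patterns, config.min_periods)
        tables = build_length_tables(stage1, segments)
        stage2 = filter_by_length(stage1, tables, segments, config.min_periods)
    except Exception as exc:
        raise PipelineError(f"day filtering: {exc}") from exc

    # -- collaborative clustering -------------------------------------------
    try:
        candidate_ids = sorted(stage2.day_ids)
        kmeans_pass: dict[datetime.date, bool] = {d: True for d in candidate_ids}
        agg_pass: dict[datetime.date, bool] = {d: True for d in candidate_ids}
        variant_labels: dict[tuple[datetime.date, str], int] = {}
        k_report: dict[str, dict] = {}
        for period in PERIODS:
            vectors = build_vectors(segments, candidate_ids, period)
            if len(vectors) < 4:
                continue  # too few vectors to cluster meaningfully
            k_range = (
                range(config.k_range[0], config.k_range[1] + 1)
                if config.k_range
                else None
            )
            k_km, km_res, km_rep = select_k_kmeans(vectors, k_range, config.seed)
            k_ag, ag_res, ag_rep = select_k_agglomerative(vectors, k_range)
            retained_km, _ = centroid_ratio_filter(vectors, km_res, config.alpha)
            retained_ag, _ = representative_cluster_filter(
                vectors, ag_res, config.min_size_frac
            )
            for vec, label in zip(vectors, km_res.labels):
                variant_labels[(vec.day_id, vec.period)] = int(label)
            for vec in vectors:
                key = (vec.day_id, vec.period)
                if key not in retained_km:
                    kmeans_pass[vec.day_id] = False
                if key not in retained_ag:
                    agg_pass[vec.day_id] = False
            k_report[period] = {
                "kmeans_k": k_km,
                "agglomerative_k": k_ag,
                "kmeans_scan": km_rep,
                "agglomerative_scan": ag_rep,
            }
        km_set = FilteredDaySet(day_ids={d for d, ok in kmeans_pass.items() if ok})
        ag_set = FilteredDaySet(day_ids={d for d, ok in agg_pass.items() if ok})
        surviving = combine(km_set, ag_set, config.combine_mode)
    except Exception as exc:
        raise PipelineError(f"clustering: {exc}") from exc

    # -- routine + coverage --------------------------------------------------
    try:
        routine = build_routine(
            sorted(surviving.day_ids),
            segments,
            patterns_by_period=patterns,
            variant_labels=variant_labels,
            alpha=config.alpha,
            mandatory_frac=config.mandatory_frac,
            optional_frac=config.optional_frac,
            overlap_frac=config.overlap_frac,
            category_bounds=config.category_bounds,
        )
    except RoutineError as exc:
        raise PipelineError(f"routine building: {exc}") from exc
    cov_all = coverage(routine, segments)
    cov_train = coverage(routine, {d: segments[d] for d in train_ids})
    cov_eval = (
        coverage(routine, {d.day_id: segments[d.day_id] for d in eval_days})
        if eval_days
        else None
    )

    result = PipelineResult(
        routine=routine,
        coverage_all=cov_all,
        coverage_train=cov_train,
        coverage_eval=cov_eval,
        surviving=surviving,
        kmeans_days=km_set,
        agglomerative_days=ag_set,
    )
    result.artifacts = {
        "patterns": patterns_to_json(patterns),
        "stage1_days": sorted(d.isoformat() for d in stage1.day_ids),
        "stage2_days": sorted(d.isoformat() for d in stage2.day_ids),
        "kmeans_days": sorted(d.isoformat() for d in km_set.day_ids),
        "agglomerative_days": sorted(d.isoformat() for d in ag_set.day_ids),
        "surviving_days": sorted(d.isoformat() for d in surviving.day_ids),
        "k_selection": k_report,
        "routine": routine.to_records(),
        "coverage": {
            "all": {"covered": cov_all.covered_days, "total": cov_all.total_days,
                    "percent": round(cov_all.coverage, 2)},
            "train": {"covered": cov_train.covered_days, "total": cov_train.total_days,
                      "percent": round(cov_train.coverage, 2)},
            "eval": None if cov_eval is None else {
                "covered": cov_eval.covered_days, "total": cov_eval.total_days,
                "percent": round(cov_eval.coverage, 2)},
        },
    }
    result.manifest = {
        "package": "routinemine",
        "version": __version__,
        "config": config.to_dict(),
        "n_days": len(days),
        "n_train_days": len(train_days),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, payload in result.artifacts.items():
            (out / f"{name}.json").write_text(json.dumps(payload, indent=2, default=str))
        (out / "manifest.json").write_text(
            json.dumps(result.manifest, indent=2, default=str)
        )
    return result
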