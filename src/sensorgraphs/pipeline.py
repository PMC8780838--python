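"""End-to-end orchestration: events -> graphs -> baseline -> pd -> trends.

``analyze_participant`` turns one event log into a difference series:
segment into civil days, build masked daily matrices, average the first k
valid (present) days into the baseline, compute pd for every later day, and
drop declared absence days.  ``analyze_cohort`` repeats this per
participant, applies the participant-level exclusion criteria, fits pooled
group trends, and compares the two groups' fitted activity with the
signed-rank test.  ``run_pipeline`` is the file-based wrapper used by the
command line: it reads a dataset directory, writes every intermediate
artifact and a manifest, and is byte-reproducible for fixed inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from datetime import date as Date
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .difference import (
    BaselineMatrix,
    DifferenceSeries,
    compute_baseline,
    daily_series,
    make_weight_matrix,
    write_series,
)
from .errors import ContentError, InsufficientDataError
from .events import (
    EventLog,
    FlatTopology,
    read_assessments,
    read_event_log,
    read_topology,
    split_by_day,
)
from .graphs import build_daily_matrix, mask_impossible, write_adjacency
from .preprocess import (
    ExclusionReport,
    ParticipantStatus,
    filter_absence_days,
    filter_participants,
    read_status,
)
from .trends import (
    GroupComparison,
    GroupTrend,
    TrendFit,
    compare_group_fits,
    fitted_change,
    group_assessment_trend,
    group_trend,
)

log = logging.getLogger("sensorgraphs")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; the manifest records it all."""

    input_dir: str = ""
    output_dir: str = "results"
    baseline_days: int = 7
    diag_weight: float = 1.0
    offdiag_weight: float = 1.5
    alpha: float = 0.01
    zone: str = "UTC"
    window_days: int | None = None
    write_daily_matrices: bool = False
    seed: int | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.baseline_days < 1:
            raise ContentError("baseline window must be >= 1 day")
        if self.diag_weight <= 0 or self.offdiag_weight <= 0:
            raise ContentError("weights must be positive")
        if not 0 < self.alpha < 1:
            raise ContentError("alpha must be in (0, 1)")


@dataclass
class ParticipantAnalysis:
    """One participant's daily matrices condensed into a pd series."""

    participant_id: str
    series: DifferenceSeries
    baseline: BaselineMatrix
    dated_matrices: list
    n_days_built: int
    n_days_absence_filtered: int
    masked_mass: float
    n_events: int


@dataclass
class CohortAnalysis:
    analyses: dict
    group_trends: dict
    comparison: GroupComparison | None
    exclusion_report: ExclusionReport
    common_window_days: int
    n_days_analyzed: int
    n_days_absence_filtered: int
    assessment_trends: dict = field(default_factory=dict)
    alpha: float = 0.01

    @property
    def fitted_changes(self) -> dict[str, float]:
        """Total fitted pd change of each group over the common window."""
        return {
            g: fitted_change(t.fit, self.common_window_days)
            for g, t in self.group_trends.items()
        }


def analyze_participant(
    participant_log: EventLog,
    topology: FlatTopology,
    status: ParticipantStatus | None = None,
    *,
    baseline_days: int = 7,
    diag_weight: float = 1.0,
    offdiag_weight: float = 1.5,
    zone: str = "UTC",
) -> ParticipantAnalysis:
    """Difference series of one participant against their own first week.

    Every daily matrix is masked (impossible transitions zeroed) before any
    aggregation.  The baseline averages the first ``baseline_days`` *valid*
    days — days with events that are not inside a declared absence interval
    — and those days are excluded from the series, as are absence days.
    """
    days = split_by_day(participant_log, zone)
    W = make_weight_matrix(topology.n, diag_weight, offdiag_weight)
    dated = []
    masked_total = 0.0
    for day in days:
        unmasked = build_daily_matrix(day, topology, mask=False)
        matrix, removed = mask_impossible(unmasked, topology)
        masked_total += removed
        dated.append((day.date, matrix))

    is_absent = status.is_absent if status is not None else (lambda d: False)
    valid = [(d, m) for d, m in dated if not is_absent(d)]
    if len(valid) < baseline_days:
        raise InsufficientDataError(
            f"{participant_log.participant_id}: {len(valid)} valid days, "
            f"need {baseline_days} for the baseline"
        )
    base_pairs = valid[:baseline_days]
    baseline = compute_baseline(
        [m for _, m in base_pairs], baseline_days, dates=[d for d, _ in base_pairs]
    )
    base_dates = set(baseline.dates)
    rest = [(d, m) for d, m in dated if d not in base_dates]
    series = daily_series(
        baseline, rest, W, participant_id=participant_log.participant_id
    )
    if status is not None:
        series, n_removed = filter_absence_days(series, status)
    else:
        n_removed = 0
    return ParticipantAnalysis(
        participant_id=participant_log.participant_id,
        series=series,
        baseline=baseline,
        dated_matrices=dated,
        n_days_built=len(dated),
        n_days_absence_filtered=n_removed,
        masked_mass=masked_total,
        n_events=len(participant_log),
    )


def analyze_cohort(
    logs: dict,
    topologies: dict,
    statuses: dict,
    assessments=None,
    *,
    baseline_days: int = 7,
    diag_weight: float = 1.0,
    offdiag_weight: float = 1.5,
    alpha: float = 0.01,
    window_days: int | None = None,
    zone: str = "UTC",
) -> CohortAnalysis:
    """Full group-level analysis of a cohort of event logs.

    Applies the participant exclusion criteria, computes per-participant
    difference series, pools them into per-group trends, and runs the
    signed-rank comparison of the two fitted activity lines on their common
    day window.
    """
    included, exclusions = filter_participants(list(statuses.values()))
    log.info("participants: %d included, %d excluded", len(included), exclusions.n_excluded)

    analyses: dict[str, ParticipantAnalysis] = {}
    groups: dict[str, str] = {}
    for status in included:
        pid = status.participant_id
        if pid not in logs:
            raise ContentError(f"no event log for participant {pid!r}")
        analyses[pid] = analyze_participant(
            logs[pid],
            topologies[pid],
            status,
            baseline_days=baseline_days,
            diag_weight=diag_weight,
            offdiag_weight=offdiag_weight,
            zone=zone,
        )
        groups[pid] = status.group

    series_map = {pid: a.series for pid, a in analyses.items()}
    trends = group_trend(series_map, groups, window_days=window_days)

    comparison = None
    common_window = 0
    if len(trends) >= 2:
        names = sorted(trends, key=lambda g: (g != "intervention", g))
        a, b = trends[names[0]], trends[names[1]]
        common_window = min(a.window_days, b.window_days)
        t = np.arange(common_window, dtype=float)
        comparison = compare_group_fits(a.fit.predict(t), b.fit.predict(t))
        log.info(
            "signed-rank comparison (%s vs %s): W=%.1f z=%.2f p=%.3g over %d d",
            names[0], names[1], comparison.w_statistic, comparison.z,
            comparison.p_value, common_window,
        )
    elif trends:
        common_window = next(iter(trends.values())).window_days

    assessment_trends = {}
    if assessments:
        for metric in ("sppb", "tug"):
            assessment_trends[metric] = group_assessment_trend(
                assessments, groups, metric
            )

    return CohortAnalysis(
        analyses=analyses,
        group_trends=trends,
        comparison=comparison,
        exclusion_report=exclusions,
        common_window_days=int(common_window),
        n_days_analyzed=sum(len(a.series) for a in analyses.values()),
        n_days_absence_filtered=sum(
            a.n_days_absence_filtered for a in analyses.values()
        ),
        assessment_trends=assessment_trends,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# file-based run


def load_dataset(input_dir) -> tuple[dict, dict, dict, list]:
    """Load a dataset directory (events/, topologies/, statuses/, assessments)."""
    root = Path(input_dir)
    missing = [
        str(root / sub)
        for sub in ("events", "topologies", "statuses")
        if not (root / sub).is_dir()
    ]
    if missing:
        raise ContentError(f"dataset incomplete, missing: {missing}")
    logs, topologies, statuses = {}, {}, {}
    for event_file in sorted((root / "events").glob("*.csv")):
        pid = event_file.stem
        logs[pid] = read_event_log(event_file)
        topo_file = root / "topologies" / f"{pid}.json"
        status_file = root / "statuses" / f"{pid}.json"
        for needed in (topo_file, status_file):
            if not needed.exists():
                raise ContentError(f"dataset incomplete, missing: {needed}")
        topologies[pid] = read_topology(topo_file)
        statuses[pid] = read_status(status_file)
    assessments = []
    if (root / "assessments.csv").exists():
        assessments = read_assessments(root / "assessments.csv")
    return logs, topologies, statuses, assessments


def run_pipeline(config: RunConfig) -> dict:
    """Run the whole analysis from a dataset directory and write artifacts.

    Outputs under ``config.output_dir``: per-participant baseline matrices
    and difference-series CSVs, a group trend report CSV, the comparison
    JSON, and ``manifest.json`` recording the configuration, the package
    version and per-stage counts.  Same config + same inputs give identical
    outputs.
    """
    logging.basicConfig(level=config.log_level)
    logs, topologies, statuses, assessments = load_dataset(config.input_dir)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    result = analyze_cohort(
        logs,
        topologies,
        statuses,
        assessments,
        baseline_days=config.baseline_days,
        diag_weight=config.diag_weight,
        offdiag_weight=config.offdiag_weight,
        alpha=config.alpha,
        window_days=config.window_days,
        zone=config.zone,
    )

    for pid, analysis in result.analyses.items():
        write_adjacency(analysis.baseline.matrix, out / f"baseline_{pid}.csv")
        write_series(analysis.series, out / f"series_{pid}.csv")
        if config.write_daily_matrices:
            daily_dir = out / "daily" / pid
            daily_dir.mkdir(parents=True, exist_ok=True)
            for date, matrix in analysis.dated_matrices:
                write_adjacency(matrix, daily_dir / f"{date.isoformat()}.csv")

    trend_rows = [
        {
            "group": g,
            "slope_per_day": t.fit.slope,
            "intercept": t.fit.intercept,
            "fitted_change": result.fitted_changes[g],
            "window_days": result.common_window_days,
            "n_participants": t.n_participants,
        }
        for g, t in sorted(result.group_trends.items())
    ]
    pd.DataFrame(trend_rows).to_csv(out / "trend_report.csv", index=False)

    if result.comparison is not None:
        with open(out / "comparison.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "W": result.comparison.w_statistic,
                    "z": result.comparison.z,
                    "p": result.comparison.p_value,
                    "n_pairs": result.comparison.n_pairs,
                    "alpha": config.alpha,
                    "significant": bool(
                        result.comparison.p_value < config.alpha
                    ),
                },
                fh,
                indent=2,
            )

    config_doc = asdict(config)
    manifest = {
        "package_version": __version__,
        "config": config_doc,
        "config_hash": hashlib.sha256(
            json.dumps(config_doc, sort_keys=True).encode()
        ).hexdigest(),
        "n_participants_included": len(result.analyses),
        "n_participants_excluded": result.exclusion_report.n_excluded,
        "n_days_analyzed": result.n_days_analyzed,
        "n_days_absence_filtered": result.n_days_absence_filtered,
        "common_window_days": result.common_window_days,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    log.info(
        "pipeline done: %d participants, %d analysis days (%d absence-filtered)",
        len(result.analyses), result.n_days_analyzed, result.n_days_absence_filtered,
    )
    return manifest
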