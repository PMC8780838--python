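"""Trend fitting and group comparison for activity and assessment series.

The tendency of a per-day series (pd values, or relative assessment scores)
is summarised by ordinary least squares: the best parameters (a, b) of the
line y = a*t + b, with t in days since the series start.  A group-level
trend pools all (day-index, value) points of the group's participants into
one fit and evaluates the fitted line on each day of the group's common
observation window.  Two groups are then compared by a Wilcoxon signed-rank
test on the day-paired fitted values, using the large-sample normal
approximation with continuity correction.

Assessment series are reported relative to their first (baseline) value:
for the SPPB a positive relative value is an improvement; for the TUG a
negative one is (less time needed), and the orientation is deliberately
preserved rather than flipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as Date
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContentError, FitError, InsufficientDataError
from .events import AssessmentRecord
from .difference import DifferenceSeries

#: Sample size above which the signed-rank test switches to the normal
#: approximation (below it, the exact null distribution is used).
NORMAL_APPROX_MIN_N = 25


@dataclass(frozen=True)
class TrendFit:
    """Least-squares line y = slope * t + intercept over day offsets t."""

    slope: float
    intercept: float
    n_points: int
    rss: float

    def predict(self, t) -> np.ndarray:
        return self.slope * np.asarray(t, dtype=float) + self.intercept


@dataclass(frozen=True)
class GroupTrend:
    """A group's pooled fit and its fitted line on the common window."""

    group: str
    fit: TrendFit
    fitted: np.ndarray  # fitted value on each day 0..window-1
    window_days: int
    n_participants: int


@dataclass(frozen=True)
class GroupComparison:
    """Signed-rank comparison of two day-paired fitted series."""

    w_statistic: float  # positive-rank sum W+
    z: float
    p_value: float
    n_pairs: int
    degenerate: bool = False


@dataclass(frozen=True)
class RelativeAssessmentSeries:
    """Assessment values minus the first (baseline) value; first entry is 0."""

    participant_id: str
    metric: str
    dates: tuple
    values: tuple


def fit_linear_trend(
    values: Sequence[float],
    *,
    x: Sequence[float] | None = None,
    dates: Sequence[Date] | None = None,
) -> TrendFit:
    """Ordinary least squares line through a dated or indexed series.

    Exactly one of ``x`` (numeric abscissae) or ``dates`` may be given; with
    ``dates`` the abscissa is calendar days since the first date, and with
    neither it is 0, 1, 2, ...  Requires at least two points with at least
    two distinct abscissae; collinear input is recovered exactly.
    """
    y = np.asarray(values, dtype=float)
    if x is not None and dates is not None:
        raise ContentError("pass either x or dates, not both")
    if dates is not None:
        first = dates[0]
        t = np.array([(d - first).days for d in dates], dtype=float)
    elif x is not None:
        t = np.asarray(x, dtype=float)
    else:
        t = np.arange(len(y), dtype=float)
    if len(t) != len(y):
        raise ContentError("abscissae and values length mismatch")
    if len(y) < 2 or len(np.unique(t)) < 2:
        raise FitError(
            f"need >= 2 points with >= 2 distinct abscissae (got {len(y)})"
        )
    slope, intercept = np.polyfit(t, y, 1)
    residuals = y - (slope * t + intercept)
    return TrendFit(
        slope=float(slope),
        intercept=float(intercept),
        n_points=len(y),
        rss=float(residuals @ residuals),
    )


def series_trend(series: DifferenceSeries) -> TrendFit:
    """Trend of a difference series over days since its first valid day."""
    return fit_linear_trend(series.pd_values, x=series.day_offsets())


def fitted_change(fit: TrendFit, window_days: float) -> float:
    """Total change of the fitted line over a window: slope * window."""
    if window_days <= 0:
        raise ContentError(f"window {window_days} must be positive")
    return fit.slope * float(window_days)


def group_trend(
    series_by_participant: Mapping[str, DifferenceSeries],
    groups: Mapping[str, str],
    *,
    window_days: int | None = None,
    method: str = "pooled",
) -> dict[str, GroupTrend]:
    """Fit one trend per group from its participants' series.

    With ``method="pooled"`` (default) all (day-offset, pd) points of a
    group enter a single least-squares fit; ``method="mean"`` averages
    per-participant fits instead.  Each participant's day offset counts from
    their own first valid day.  The fitted line is evaluated on the common
    window [0, w), where w defaults to the shortest participant span within
    the group.
    """
    if method not in ("pooled", "mean"):
        raise ContentError(f"unknown aggregation method {method!r}")
    by_group: dict[str, list[DifferenceSeries]] = {}
    for pid, series in series_by_participant.items():
        if pid not in groups:
            raise ContentError(f"participant {pid!r} has no group assignment")
        by_group.setdefault(groups[pid], []).append(series)

    out: dict[str, GroupTrend] = {}
    for group, members in by_group.items():
        if not members:
            raise InsufficientDataError(f"group {group!r} is empty")
        spans = [int(s.day_offsets()[-1]) + 1 for s in members if len(s)]
        if not spans:
            raise InsufficientDataError(f"group {group!r} has no observed days")
        window = window_days if window_days is not None else min(spans)
        if method == "pooled":
            t = np.concatenate([s.day_offsets() for s in members])
            y = np.concatenate([s.pd_values for s in members])
            fit = fit_linear_trend(y, x=t)
        else:
            fits = [series_trend(s) for s in members]
            n_total = sum(f.n_points for f in fits)
            fit = TrendFit(
                slope=float(np.mean([f.slope for f in fits])),
                intercept=float(np.mean([f.intercept for f in fits])),
                n_points=n_total,
                rss=float("nan"),
            )
        days = np.arange(window, dtype=float)
        out[group] = GroupTrend(
            group=group,
            fit=fit,
            fitted=fit.predict(days),
            window_days=int(window),
            n_participants=len(members),
        )
    return out


def signed_rank_statistic(differences: np.ndarray) -> float:
    """Positive-rank sum W+ of nonzero paired differences (average ranks).

    When every difference has the same sign, W+ equals n(n+1)/2 — the
    largest value the statistic can take.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    if len(d) == 0:
        return 0.0
    ranks = stats.rankdata(np.abs(d))
    return float(ranks[d > 0].sum())


def compare_group_fits(
    fitted_a: Sequence[float], fitted_b: Sequence[float]
) -> GroupComparison:
    """Wilcoxon signed-rank test on day-paired fitted activity values.

    Pairs the two series by day index and tests the null hypothesis that the
    paired differences are symmetric about zero.  For more than
    ``NORMAL_APPROX_MIN_N`` pairs the normal approximation with continuity
    correction supplies z and p; ties in |difference| get average ranks.
    All-zero differences yield the degenerate convention p = 1.
    """
    a = np.asarray(fitted_a, dtype=float)
    b = np.asarray(fitted_b, dtype=float)
    if a.shape != b.shape:
        raise ContentError(f"length mismatch: {a.shape} vs {b.shape}")
    if len(a) < 1:
        raise InsufficientDataError("need at least one pair")
    d = a - b
    w_plus = signed_rank_statistic(d)
    if np.all(d == 0):
        return GroupComparison(
            w_statistic=w_plus, z=0.0, p_value=1.0, n_pairs=len(d), degenerate=True
        )
    nz = d[d != 0]
    method = "approx" if len(nz) > NORMAL_APPROX_MIN_N else "exact"
    res = stats.wilcoxon(a, b, method=method, correction=(method == "approx"))
    if method == "approx":
        # signed z of W+ (scipy's two-sided z-statistic loses the direction):
        # continuity-corrected normal approximation with tie correction
        n = len(nz)
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, counts = np.unique(np.abs(nz), return_counts=True)
        var -= (counts**3 - counts).sum() / 48.0
        z = float((w_plus - mu - 0.5 * np.sign(w_plus - mu)) / np.sqrt(var))
    else:  # small n: report the exact-test z-equivalent from the p-value
        z = float(np.sign(np.sum(np.sign(d))) * stats.norm.isf(res.pvalue / 2))
    return GroupComparison(
        w_statistic=w_plus,
        z=z,
        p_value=float(res.pvalue),
        n_pairs=int(len(d)),
    )


def relative_series(
    records: Sequence[AssessmentRecord], metric: str
) -> RelativeAssessmentSeries:
    """Assessment series relative to its first value.

    ``metric`` is ``"sppb"`` or ``"tug"``.  The first value maps to 0 and
    later values to their difference from it; the clinical orientation
    (SPPB up = better, TUG down = better) is preserved.
    """
    if metric not in ("sppb", "tug"):
        raise ContentError(f"unknown metric {metric!r}")
    if not records:
        raise InsufficientDataError("no assessment records")
    ordered = sorted(records, key=lambda r: r.date)
    pids = {r.participant_id for r in ordered}
    if len(pids) > 1:
        raise ContentError(f"records mix participants {sorted(pids)}")
    first = getattr(ordered[0], metric)
    return RelativeAssessmentSeries(
        participant_id=ordered[0].participant_id,
        metric=metric,
        dates=tuple(r.date for r in ordered),
        values=tuple(float(getattr(r, metric) - first) for r in ordered),
    )


def group_assessment_trend(
    records: Sequence[AssessmentRecord],
    groups: Mapping[str, str],
    metric: str,
) -> dict[str, TrendFit]:
    """Pooled relative-assessment trend per group (days since first visit)."""
    by_pid: dict[str, list[AssessmentRecord]] = {}
    for rec in records:
        by_pid.setdefault(rec.participant_id, []).append(rec)
    points: dict[str, list[tuple[float, float]]] = {}
    for pid, recs in by_pid.items():
        rel = relative_series(recs, metric)
        first = rel.dates[0]
        group = groups.get(pid)
        if group is None:
            continue
        for d, v in zip(rel.dates, rel.values):
            points.setdefault(group, []).append(((d - first).days, v))
    out = {}
    for group, pts in points.items():
        t, y = zip(*pts)
        try:
            out[group] = fit_linear_trend(y, x=t)
        except FitError:  # e.g. a single visit per participant
            continue
    return out
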