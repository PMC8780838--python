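"""Baseline graphs and the percent-of-baseline difference statistic.

Daily activity is compared against a personal baseline B, the entrywise mean
of the first k valid daily matrices (k = 7 by default, one week).  Both B and
the daily matrix D are elementwise weighted by a matrix W that carries 1 on
the diagonal and 1.5 off it — room *transitions* are rarer than within-room
motion but more informative about mobility, so they are up-weighted.  The
difference statistic is

    diff(B, D) = sum_ij  W_ij * (B_ij - D_ij)

and the per-day performance surrogate is that difference as a fraction of
the weighted baseline mass:

    pd = diff(B, D) / sum_ij W_ij * B_ij

pd is 0 when a day matches the baseline exactly, +1 (100 %) when a day shows
no activity at all, and negative when a day is *more* active than baseline.
``pd`` is stored as a signed fraction; CSV output renders it in percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as Date
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    ContentError,
    DegenerateBaselineError,
    InsufficientDataError,
    ParameterError,
)
from .graphs import AdjacencyMatrix

#: Default baseline window: one week of valid days.
DEFAULT_BASELINE_DAYS = 7
DEFAULT_DIAG_WEIGHT = 1.0
DEFAULT_OFFDIAG_WEIGHT = 1.5


@dataclass(frozen=True)
class WeightMatrix:
    """Constant-by-position weights: one value on the diagonal, one off it."""

    values: np.ndarray
    diag: float
    offdiag: float

    @property
    def n(self) -> int:
        return self.values.shape[0]


def make_weight_matrix(
    n: int,
    diag: float = DEFAULT_DIAG_WEIGHT,
    offdiag: float = DEFAULT_OFFDIAG_WEIGHT,
) -> WeightMatrix:
    """Build the n x n weight matrix (defaults 1 on-diagonal, 1.5 off)."""
    if n < 1:
        raise ParameterError(f"dimension {n} must be >= 1")
    if diag <= 0 or offdiag <= 0:
        raise ParameterError("weights must be strictly positive")
    W = np.full((n, n), float(offdiag))
    np.fill_diagonal(W, float(diag))
    return WeightMatrix(W, float(diag), float(offdiag))


@dataclass
class BaselineMatrix:
    """Entrywise mean of the first k valid daily matrices, with provenance."""

    matrix: AdjacencyMatrix
    dates: tuple = ()
    window: int = DEFAULT_BASELINE_DAYS

    @property
    def labels(self) -> tuple[str, ...]:
        return self.matrix.labels

    @property
    def values(self) -> np.ndarray:
        return self.matrix.values


@dataclass(frozen=True)
class DifferenceResult:
    """One day's comparison to baseline: raw weighted difference and pd."""

    raw: float
    pd: float  # signed fraction; multiply by 100 for percent
    date: Date | None = None


@dataclass
class DifferenceSeries:
    """Ordered per-day pd values of one participant (fractions, not percent)."""

    participant_id: str
    dates: tuple
    pd_values: np.ndarray
    baseline_dates: tuple = ()

    def __post_init__(self) -> None:
        self.dates = tuple(self.dates)
        self.pd_values = np.asarray(self.pd_values, dtype=float)
        if len(self.dates) != len(self.pd_values):
            raise ContentError("dates and values length mismatch")
        if any(b >= a for a, b in zip(self.dates[1:], self.dates[:-1])):
            raise ContentError("series dates must be strictly increasing")

    def __len__(self) -> int:
        return len(self.dates)

    def day_offsets(self) -> np.ndarray:
        """Calendar days since the first date of the series."""
        if not self.dates:
            return np.array([], dtype=float)
        first = self.dates[0]
        return np.array([(d - first).days for d in self.dates], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "date": [d.isoformat() for d in self.dates],
                "pd_percent": self.pd_values * 100.0,
            }
        )


def compute_baseline(
    dailies: Sequence[AdjacencyMatrix],
    k: int = DEFAULT_BASELINE_DAYS,
    dates: Sequence | None = None,
) -> BaselineMatrix:
    """Average the first ``k`` daily matrices entrywise into a baseline.

    Raises :class:`InsufficientDataError` with fewer than ``k`` dailies and
    :class:`ContentError` on label disagreement.
    """
    if k < 1:
        raise ParameterError(f"baseline window {k} must be >= 1")
    if len(dailies) < k:
        raise InsufficientDataError(
            f"need {k} daily matrices for the baseline, got {len(dailies)}"
        )
    head = dailies[:k]
    labels = head[0].labels
    for m in head[1:]:
        if m.labels != labels:
            raise ContentError("daily matrices carry different room labels")
    mean = np.mean([m.values for m in head], axis=0)
    provenance = tuple(dates[:k]) if dates is not None else ()
    return BaselineMatrix(AdjacencyMatrix(labels, mean), provenance, k)


def _values(M) -> np.ndarray:
    return M.values if not isinstance(M, np.ndarray) else M


def _check_shapes(B, D, W: WeightMatrix) -> None:
    b, d = _values(B), _values(D)
    if b.shape != d.shape or b.shape != W.values.shape:
        raise ContentError(
            f"shape mismatch: baseline {b.shape}, daily {d.shape}, weights "
            f"{W.values.shape}"
        )
    b_labels = getattr(B, "labels", None)
    d_labels = getattr(D, "labels", None)
    if b_labels is not None and d_labels is not None and b_labels != d_labels:
        raise ContentError("baseline and daily matrix labels differ")


def weighted_total(M, W: WeightMatrix) -> float:
    """Total weighted mass sum_ij W_ij * M_ij."""
    return float((W.values * _values(M)).sum())


def graph_difference(B, D, W: WeightMatrix | None = None) -> float:
    """Weighted elementwise difference sum_ij W_ij * (B_ij - D_ij).

    Linear in both arguments; positive when the day carries less weighted
    mass than the baseline.
    """
    if W is None:
        W = make_weight_matrix(_values(B).shape[0])
    _check_shapes(B, D, W)
    return float((W.values * (_values(B) - _values(D))).sum())


def percent_difference(
    B,
    D,
    W: WeightMatrix | None = None,
    date: Date | None = None,
) -> DifferenceResult:
    """The difference as a signed fraction of the weighted baseline total.

    pd = diff(B, D) / sum_ij W_ij * B_ij.  Raises
    :class:`DegenerateBaselineError` when the weighted baseline total is not
    positive (an all-zero baseline has no meaningful percent scale).
    """
    if W is None:
        W = make_weight_matrix(_values(B).shape[0])
    raw = graph_difference(B, D, W)
    denom = weighted_total(B, W)
    if denom <= 0:
        raise DegenerateBaselineError(
            f"weighted baseline total {denom} is not positive"
        )
    return DifferenceResult(raw=raw, pd=raw / denom, date=date)


def daily_series(
    baseline: BaselineMatrix,
    dailies: Sequence[tuple],
    W: WeightMatrix | None = None,
    participant_id: str = "",
) -> DifferenceSeries:
    """Compute pd for a dated sequence of daily matrices.

    ``dailies`` is a sequence of ``(date, AdjacencyMatrix)`` pairs; dates
    must be unique.  The result is ordered by date.
    """
    if W is None:
        W = make_weight_matrix(baseline.values.shape[0])
    dates = [d for d, _ in dailies]
    if len(set(dates)) != len(dates):
        raise ContentError("duplicate dates in daily matrices")
    ordered = sorted(dailies, key=lambda pair: pair[0])
    values = [percent_difference(baseline, M, W, date=d).pd for d, M in ordered]
    return DifferenceSeries(
        participant_id=participant_id,
        dates=tuple(d for d, _ in ordered),
        pd_values=np.array(values),
        baseline_dates=tuple(baseline.dates),
    )


def write_series(series: DifferenceSeries, path) -> None:
    """Write a difference series CSV (``participant_id,date,pd_percent``)."""
    series.to_frame().to_csv(path, index=False)


def read_series(path) -> DifferenceSeries:
    raw = pd.read_csv(path, dtype={"participant_id": str})
    missing = {"participant_id", "date", "pd_percent"} - set(raw.columns)
    if missing:
        raise ContentError(f"{path}: missing columns {sorted(missing)}")
    pid = str(raw["participant_id"].iloc[0]) if len(raw) else ""
    dates = tuple(pd.Timestamp(d).date() for d in raw["date"])
    return DifferenceSeries(
        participant_id=pid,
        dates=dates,
        pd_values=raw["pd_percent"].to_numpy(dtype=float) / 100.0,
    )
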