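"""Participant- and day-level filtering, and the cohort bias check.

A longitudinal in-home study loses participants (death, moving to a nursing
home, a fall that changes mobility for reasons unrelated to the outcome
under study) and loses days (vacation, short-term care, hospitalization).
Both filters live here, driven by per-participant status metadata: the
recorded absence intervals are authoritative, while the low-event-count
detector only *suggests* candidate absence days for review.

After exclusions, the analysed sub-cohort must be checked for selection
bias: each metric-scale characteristic (age, frailty index, SPPB, TUG) is
compared between two groups with an unpaired two-sample rank test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from datetime import date as Date, timedelta
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContentError, InsufficientDataError
from .difference import DifferenceSeries

#: Advisory threshold: days with fewer events than this are absence candidates.
DEFAULT_ABSENCE_EVENT_THRESHOLD = 10.0

EXCLUSION_CRITERIA = (
    "deceased",
    "living-situation-change",
    "mobility-compromising-incident",
)


@dataclass(frozen=True)
class AbsenceInterval:
    """A closed date interval during which the participant was away."""

    start: Date
    end: Date
    reason: str = "other"

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ContentError(f"absence interval ends before it starts: {self}")

    def __contains__(self, day: Date) -> bool:
        return self.start <= day <= self.end

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1


@dataclass
class ParticipantStatus:
    """Group assignment, exclusion flags (with onset dates) and absences."""

    participant_id: str
    group: str = "intervention"  # "intervention" | "control"
    deceased_on: Date | None = None
    living_change_on: Date | None = None
    mobility_incident_on: Date | None = None
    absences: tuple = ()

    def __post_init__(self) -> None:
        if self.group not in ("intervention", "control"):
            raise ContentError(f"unknown group {self.group!r}")
        self.absences = tuple(
            sorted(self.absences, key=lambda iv: (iv.start, iv.end))
        )
        for prev, nxt in zip(self.absences, self.absences[1:]):
            if nxt.start <= prev.end:
                raise ContentError(
                    f"overlapping absence intervals {prev} and {nxt}"
                )

    @property
    def exclusion_criterion(self) -> str | None:
        """Name of the first exclusion criterion that applies, or None."""
        for criterion, onset in zip(
            EXCLUSION_CRITERIA,
            (self.deceased_on, self.living_change_on, self.mobility_incident_on),
        ):
            if onset is not None:
                return criterion
        return None

    def is_absent(self, day: Date) -> bool:
        return any(day in interval for interval in self.absences)


@dataclass
class ExclusionReport:
    """Which participants were dropped and by which criterion."""

    entries: tuple = ()  # (participant_id, criterion) pairs

    @property
    def n_excluded(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.entries), columns=["participant_id", "criterion"]
        )


def filter_participants(
    statuses: Sequence[ParticipantStatus],
) -> tuple[list[ParticipantStatus], ExclusionReport]:
    """Drop participants carrying any exclusion flag.

    Returns the included statuses (input order preserved) and a report naming
    the criterion behind each exclusion.
    """
    included, excluded = [], []
    for status in statuses:
        criterion = status.exclusion_criterion
        if criterion is None:
            included.append(status)
        else:
            excluded.append((status.participant_id, criterion))
    return included, ExclusionReport(tuple(excluded))


def filter_absence_days(
    series: DifferenceSeries, status: ParticipantStatus
) -> tuple[DifferenceSeries, int]:
    """Remove series days falling inside any declared absence interval.

    Days outside the declared intervals are never touched.  Returns the
    filtered series and the number of removed days.
    """
    keep = np.array([not status.is_absent(d) for d in series.dates], dtype=bool)
    removed = int((~keep).sum())
    filtered = DifferenceSeries(
        participant_id=series.participant_id,
        dates=tuple(d for d, k in zip(series.dates, keep) if k),
        pd_values=series.pd_values[keep],
        baseline_dates=series.baseline_dates,
    )
    return filtered, removed


def detect_absence_candidates(
    dated_matrices: Sequence[tuple],
    threshold: float = DEFAULT_ABSENCE_EVENT_THRESHOLD,
) -> list[Date]:
    """Flag dates whose implied event count falls below ``threshold``.

    The unmasked matrix total of a day with m events is m - 1, so the implied
    count is total + 1.  Candidates are advisory: real absences are filtered
    from study records, because a very quiet day can also be genuine
    inactivity.
    """
    flagged = []
    for date, matrix in dated_matrices:
        implied_events = matrix.total + 1.0
        if implied_events < threshold:
            flagged.append(date)
    return flagged


def cohort_bias_check(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-variable two-sample Mann-Whitney rank test between two cohorts.

    Every column common to both tables is compared; the verdict is
    ``"different"`` when p < alpha, else ``"same"``.  A column with fewer
    than two values in either group raises
    :class:`InsufficientDataError`.
    """
    common = [c for c in group_a.columns if c in group_b.columns]
    if not common:
        raise ContentError("the two cohort tables share no variables")
    rows = []
    for var in common:
        a = pd.to_numeric(group_a[var], errors="coerce").dropna().to_numpy()
        b = pd.to_numeric(group_b[var], errors="coerce").dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise InsufficientDataError(
                f"variable {var!r}: need >= 2 values per group "
                f"(got {len(a)} and {len(b)})"
            )
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append(
            {
                "variable": var,
                "n_a": len(a),
                "n_b": len(b),
                "statistic": float(stat),
                "p_value": float(p),
                "verdict": "different" if p < alpha else "same",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# status JSON I/O


def _date_or_none(value):
    return None if value is None else Date.fromisoformat(value)


def read_status(path) -> ParticipantStatus:
    """Load a participant-status JSON file."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    flags = doc.get("flags", {})
    absences = tuple(
        AbsenceInterval(
            start=Date.fromisoformat(iv["start"]),
            end=Date.fromisoformat(iv["end"]),
            reason=iv.get("reason", "other"),
        )
        for iv in doc.get("absences", [])
    )
    return ParticipantStatus(
        participant_id=str(doc["participant_id"]),
        group=doc.get("group", "intervention"),
        deceased_on=_date_or_none(flags.get("deceased")),
        living_change_on=_date_or_none(flags.get("living-situation-change")),
        mobility_incident_on=_date_or_none(flags.get("mobility-compromising-incident")),
        absences=absences,
    )


def write_status(status: ParticipantStatus, path) -> None:
    doc = {
        "participant_id": status.participant_id,
        "group": status.group,
        "flags": {
            "deceased": status.deceased_on.isoformat() if status.deceased_on else None,
            "living-situation-change": (
                status.living_change_on.isoformat() if status.living_change_on else None
            ),
            "mobility-compromising-incident": (
                status.mobility_incident_on.isoformat()
                if status.mobility_incident_on
                else None
            ),
        },
        "absences": [
            {"start": iv.start.isoformat(), "end": iv.end.isoformat(), "reason": iv.reason}
            for iv in status.absences
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)
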