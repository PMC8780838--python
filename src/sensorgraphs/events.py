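"""Sensor event logs, flat topologies and assessment records.

The raw observable of an ambient monitoring installation is a chronological
log of PIR (passive infrared) motion-sensor firings.  Each sensor sits in one
room of a single-resident flat and, after firing, stays blind for an 8 s
cool-down, so two firings of the same sensor are always at least 8 s apart.
This module provides the data types for those logs, for the flat topology
(rooms, sensor placement, which direct room-to-room transitions are
physically possible) and for the monthly geriatric assessment records (SPPB
points and TUG seconds), together with CSV/JSON I/O, validation and
segmentation of a log into civil days.

File dialects
-------------
* Event log CSV: header ``timestamp,participant_id,sensor_id``, one firing
  per row, ISO 8601 timestamps (offset optional; offset-free stamps are
  interpreted in a configurable zone, UTC by default).
* Topology JSON: ``{"rooms": [...], "sensors": {"<id>": "<room>"},
  "connections": [["roomA", "roomB"], ...]}``.  Connections are undirected
  in the file and expanded to both ordered pairs; loops (staying in a room)
  are always possible and added automatically.
* Assessments CSV: header ``participant_id,date,sppb,tug``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date as Date
from typing import Iterable, Mapping, NamedTuple, Sequence
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd

from .errors import (
    ContentError,
    EventLogParseError,
    TopologySchemaError,
)

#: PIR hardware cool-down: the same sensor cannot fire twice within this gap.
PIR_COOLDOWN_SECONDS = 8.0

EVENT_LOG_COLUMNS = ("timestamp", "participant_id", "sensor_id")
ASSESSMENT_COLUMNS = ("participant_id", "date", "sppb", "tug")


def _as_zone(zone) -> ZoneInfo:
    if zone is None:
        return ZoneInfo("UTC")
    if isinstance(zone, str):
        return ZoneInfo(zone)
    return zone


class SensorEvent(NamedTuple):
    """A single PIR firing: when, and which sensor."""

    timestamp: pd.Timestamp
    sensor_id: str


def _event_frame(timestamps, sensor_ids, zone) -> pd.DataFrame:
    s = pd.Series(list(timestamps))
    if s.dtype == object and len(s) and isinstance(s.iloc[0], str):
        ts = pd.to_datetime(s, format="ISO8601")
    else:
        ts = pd.to_datetime(s)
    tz = _as_zone(zone)
    ts = ts.dt.tz_localize(tz) if ts.dt.tz is None else ts.dt.tz_convert(tz)
    return pd.DataFrame(
        {"timestamp": ts, "sensor_id": [str(s) for s in sensor_ids]}
    )


@dataclass
class EventLog:
    """Chronological PIR firings of one participant.

    Events are held in a two-column DataFrame (``timestamp`` tz-aware,
    ``sensor_id`` string) sorted non-decreasing by timestamp; the ``events``
    property materialises them as :class:`SensorEvent` tuples.
    """

    participant_id: str
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"timestamp", "sensor_id"} - set(self.frame.columns)
        if missing:
            raise ContentError(f"event frame lacks columns: {sorted(missing)}")
        self.frame = self.frame.loc[:, ["timestamp", "sensor_id"]].reset_index(
            drop=True
        )

    @classmethod
    def from_events(
        cls,
        participant_id: str,
        events: Iterable[tuple],
        zone="UTC",
    ) -> "EventLog":
        """Build a log from ``(timestamp, sensor_id)`` pairs."""
        events = list(events)
        if not events:
            frame = pd.DataFrame(
                {
                    "timestamp": pd.Series([], dtype=f"datetime64[ns, {_as_zone(zone)}]"),
                    "sensor_id": pd.Series([], dtype=str),
                }
            )
            return cls(participant_id, frame)
        stamps, sensors = zip(*events)
        return cls(participant_id, _event_frame(stamps, sensors, zone))

    @property
    def events(self) -> list[SensorEvent]:
        return [
            SensorEvent(t, s)
            for t, s in zip(self.frame["timestamp"], self.frame["sensor_id"])
        ]

    @property
    def timestamps(self) -> pd.Series:
        return self.frame["timestamp"]

    @property
    def sensor_ids(self) -> np.ndarray:
        return self.frame["sensor_id"].to_numpy()

    def __len__(self) -> int:
        return len(self.frame)

    def is_sorted(self) -> bool:
        return bool(self.frame["timestamp"].is_monotonic_increasing)

    def sorted(self) -> "EventLog":
        """Return a copy sorted stably by timestamp."""
        frame = self.frame.sort_values("timestamp", kind="mergesort")
        return EventLog(self.participant_id, frame.reset_index(drop=True))


@dataclass
class DayEvents:
    """The slice of a participant's log falling on one civil date."""

    participant_id: str
    date: Date
    frame: pd.DataFrame

    @property
    def events(self) -> list[SensorEvent]:
        return [
            SensorEvent(t, s)
            for t, s in zip(self.frame["timestamp"], self.frame["sensor_id"])
        ]

    @property
    def sensor_ids(self) -> np.ndarray:
        return self.frame["sensor_id"].to_numpy()

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class FlatTopology:
    """Rooms of a flat, sensor placement and physically possible transitions.

    ``rooms`` fixes the vertex order used by every adjacency matrix built for
    this flat (row = source room, column = destination room).
    ``possible_transitions`` holds ordered room-name pairs and always contains
    every loop ``(r, r)``: staying in a room is always possible.
    """

    rooms: tuple[str, ...]
    sensor_map: Mapping[str, str]
    possible_transitions: frozenset

    def __post_init__(self) -> None:
        if len(self.rooms) < 1:
            raise TopologySchemaError("a topology needs at least one room")
        if len(set(self.rooms)) != len(self.rooms):
            raise TopologySchemaError("duplicate room names")
        known = set(self.rooms)
        for sensor, room in self.sensor_map.items():
            if room not in known:
                raise TopologySchemaError(
                    f"sensor {sensor!r} mapped to unlisted room {room!r}"
                )
        for room in self.rooms:
            if (room, room) not in self.possible_transitions:
                raise TopologySchemaError(f"missing loop for room {room!r}")
        for a, b in self.possible_transitions:
            if a not in known or b not in known:
                raise TopologySchemaError(f"transition ({a!r}, {b!r}) names unknown room")

    @classmethod
    def from_connections(
        cls,
        rooms: Sequence[str],
        sensor_map: Mapping[str, str],
        connections: Iterable[Sequence[str]] = (),
    ) -> "FlatTopology":
        """Build from undirected room connections; loops are added for free."""
        rooms = tuple(rooms)
        pairs = {(r, r) for r in rooms}
        for conn in connections:
            a, b = conn
            pairs.add((a, b))
            pairs.add((b, a))
        return cls(rooms, dict(sensor_map), frozenset(pairs))

    @property
    def n(self) -> int:
        return len(self.rooms)

    def room_index(self) -> dict[str, int]:
        return {room: i for i, room in enumerate(self.rooms)}

    def is_possible(self, src: str, dst: str) -> bool:
        return (src, dst) in self.possible_transitions

    def transition_mask(self) -> np.ndarray:
        """Boolean (n, n) array: True where the ordered transition is possible."""
        index = self.room_index()
        mask = np.zeros((self.n, self.n), dtype=bool)
        for a, b in self.possible_transitions:
            mask[index[a], index[b]] = True
        return mask

    def neighbors(self, room: str) -> tuple[str, ...]:
        """Rooms directly reachable from ``room`` (excluding the loop)."""
        return tuple(
            b for a, b in sorted(self.possible_transitions) if a == room and b != room
        )


@dataclass(frozen=True)
class AssessmentRecord:
    """One supervised mobility assessment: SPPB points and TUG seconds."""

    participant_id: str
    date: Date
    sppb: int
    tug: float
    frailty_index: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.sppb <= 12:
            raise ContentError(f"SPPB {self.sppb} outside 0..12")
        if not self.tug > 0:
            raise ContentError(f"TUG {self.tug} must be positive")
        if self.frailty_index is not None and not 0 <= self.frailty_index <= 5:
            raise ContentError(f"frailty index {self.frailty_index} outside 0..5")


@dataclass
class ValidationReport:
    """Per-class violation tallies for an event log; validation never raises."""

    unknown_sensor_rows: tuple[int, ...] = ()
    out_of_order_rows: tuple[int, ...] = ()
    cooldown_rows: tuple[int, ...] = ()

    @property
    def n_unknown_sensors(self) -> int:
        return len(self.unknown_sensor_rows)

    @property
    def n_out_of_order(self) -> int:
        return len(self.out_of_order_rows)

    @property
    def n_cooldown_violations(self) -> int:
        return len(self.cooldown_rows)

    @property
    def ok(self) -> bool:
        return not (
            self.unknown_sensor_rows or self.out_of_order_rows or self.cooldown_rows
        )


# ---------------------------------------------------------------------------
# event log I/O


def read_event_log(path, *, zone="UTC", sort: bool = True) -> EventLog:
    """Read an event-log CSV.

    Offset-free timestamps are interpreted in ``zone`` (default UTC);
    timestamps carrying an offset are converted to ``zone``.  With
    ``sort=True`` (default) rows are stably sorted by timestamp.

    Raises
    ------
    EventLogParseError
        Missing columns or an unparseable timestamp (the row is named).
    ContentError
        Rows carry more than one participant_id.
    """
    raw = pd.read_csv(path, dtype={"participant_id": str, "sensor_id": str})
    missing = set(EVENT_LOG_COLUMNS) - set(raw.columns)
    if missing:
        raise EventLogParseError(f"{path}: missing columns {sorted(missing)}")
    participants = raw["participant_id"].dropna().unique()
    if len(participants) > 1:
        raise ContentError(
            f"{path}: mixed participant_ids {sorted(participants)}"
        )
    participant_id = str(participants[0]) if len(participants) else ""

    ts = pd.to_datetime(raw["timestamp"], format="ISO8601", errors="coerce")
    if ts.dtype == object:  # mixed offset / offset-free stamps
        ts = pd.to_datetime(raw["timestamp"], format="ISO8601", errors="coerce", utc=True)
    bad = ts.isna() & raw["timestamp"].notna()
    if bad.any() or ts.isna().any():
        row = int(np.flatnonzero(ts.isna().to_numpy())[0])
        raise EventLogParseError(
            f"{path}: row {row + 2}: unparseable timestamp "
            f"{raw['timestamp'].iloc[row]!r}"
        )
    tz = _as_zone(zone)
    ts = ts.dt.tz_localize(tz) if ts.dt.tz is None else ts.dt.tz_convert(tz)

    frame = pd.DataFrame({"timestamp": ts, "sensor_id": raw["sensor_id"].astype(str)})
    if len(frame) == 0:
        frame["sensor_id"] = frame["sensor_id"].astype(str)
    log = EventLog(participant_id, frame)
    return log.sorted() if sort else log


def write_event_log(log: EventLog, path) -> None:
    """Write a log back to the event-log CSV dialect (ISO stamps with offset)."""
    out = pd.DataFrame(
        {
            "timestamp": [t.isoformat() for t in log.frame["timestamp"]],
            "participant_id": log.participant_id,
            "sensor_id": log.frame["sensor_id"],
        }
    )
    if len(out) == 0:
        out = pd.DataFrame(columns=list(EVENT_LOG_COLUMNS))
    out.to_csv(path, index=False)


def validate_event_log(log: EventLog, topology: FlatTopology | None = None) -> ValidationReport:
    """Check a log against ordering, the 8 s cool-down, and sensor placement.

    A cool-down violation is two consecutive firings of the *same* sensor
    strictly less than 8 s apart (exactly 8 s is legal).  The log is never
    mutated and validation never raises; results come back as a
    :class:`ValidationReport` listing offending row positions.
    """
    n = len(log)
    if n == 0:
        return ValidationReport()
    ts = log.frame["timestamp"].astype("int64").to_numpy() / 1e9  # seconds
    out_of_order = tuple(int(i) + 1 for i in np.flatnonzero(np.diff(ts) < 0))

    cooldown: list[int] = []
    positions = np.arange(n)
    sensors = log.frame["sensor_id"].to_numpy()
    order = np.argsort(ts, kind="stable")
    ts_sorted, sens_sorted, pos_sorted = ts[order], sensors[order], positions[order]
    for sensor in pd.unique(sens_sorted):
        sel = sens_sorted == sensor
        gaps = np.diff(ts_sorted[sel])
        bad = np.flatnonzero(gaps < PIR_COOLDOWN_SECONDS) + 1
        cooldown.extend(int(p) for p in pos_sorted[sel][bad])

    unknown: tuple[int, ...] = ()
    if topology is not None:
        known = set(topology.sensor_map)
        unknown = tuple(
            int(i) for i, s in enumerate(sensors) if s not in known
        )
    return ValidationReport(
        unknown_sensor_rows=unknown,
        out_of_order_rows=out_of_order,
        cooldown_rows=tuple(sorted(cooldown)),
    )


def drop_cooldown_violations(log: EventLog, topology: FlatTopology | None = None) -> EventLog:
    """Return a copy with events violating the 8 s cool-down removed."""
    report = validate_event_log(log, topology)
    if not report.cooldown_rows:
        return EventLog(log.participant_id, log.frame.copy())
    keep = np.ones(len(log), dtype=bool)
    keep[list(report.cooldown_rows)] = False
    return EventLog(log.participant_id, log.frame.loc[keep].reset_index(drop=True))


def split_by_day(log: EventLog, zone="UTC") -> list[DayEvents]:
    """Partition a sorted log into per-civil-date slices.

    The day boundary is civil midnight in ``zone``; days without events are
    omitted.  Every event lands in exactly one day, and within-day order is
    the log order, so event counts are conserved.
    """
    if len(log) == 0:
        return []
    local = log.frame["timestamp"].dt.tz_convert(_as_zone(zone))
    dates = local.dt.date
    days = []
    for date, sub in log.frame.groupby(dates.to_numpy(), sort=True):
        days.append(DayEvents(log.participant_id, date, sub.reset_index(drop=True)))
    return days


# ---------------------------------------------------------------------------
# topology and assessment I/O


def read_topology(path) -> FlatTopology:
    """Load a flat-topology JSON file (see module docstring for the schema)."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    for key in ("rooms", "sensors"):
        if key not in doc:
            raise TopologySchemaError(f"{path}: missing key {key!r}")
    connections = doc.get("connections", [])
    for conn in connections:
        if len(conn) != 2:
            raise TopologySchemaError(f"{path}: connection {conn!r} is not a pair")
    try:
        return FlatTopology.from_connections(doc["rooms"], doc["sensors"], connections)
    except TopologySchemaError as exc:
        raise TopologySchemaError(f"{path}: {exc}") from exc


def write_topology(topology: FlatTopology, path) -> None:
    """Write a topology as JSON; directed pairs collapse to undirected edges."""
    undirected = sorted(
        {
            tuple(sorted((a, b)))
            for a, b in topology.possible_transitions
            if a != b
        }
    )
    doc = {
        "rooms": list(topology.rooms),
        "sensors": dict(topology.sensor_map),
        "connections": [list(pair) for pair in undirected],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)


def read_assessments(path) -> list[AssessmentRecord]:
    """Read an assessments CSV into validated records, sorted by date."""
    raw = pd.read_csv(path, dtype={"participant_id": str})
    missing = set(ASSESSMENT_COLUMNS) - set(raw.columns)
    if missing:
        raise EventLogParseError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for _, row in raw.iterrows():
        records.append(
            AssessmentRecord(
                participant_id=str(row["participant_id"]),
                date=pd.Timestamp(row["date"]).date(),
                sppb=int(row["sppb"]),
                tug=float(row["tug"]),
                frailty_index=(
                    int(row["frailty_index"])
                    if "frailty_index" in raw.columns and pd.notna(row.get("frailty_index"))
                    else None
                ),
            )
        )
    records.sort(key=lambda r: (r.participant_id, r.date))
    return records


def write_assessments(records: Sequence[AssessmentRecord], path) -> None:
    rows = [
        {
            "participant_id": r.participant_id,
            "date": r.date.isoformat(),
            "sppb": r.sppb,
            "tug": r.tug,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(ASSESSMENT_COLUMNS)).to_csv(path, index=False)
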