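"""Synthetic single-resident flats, cohorts and sensor-event streams.

The private nature of in-home monitoring data makes a generative stand-in
necessary for testing and calibration.  The model here is deliberately the
simplest process that reproduces the structure the analysis relies on:

* **Occupancy** is semi-Markov: the resident dwells in a room for a
  log-normally distributed time, then moves to a uniformly chosen adjacent
  room.  Nights are spent in the bedroom between a (jittered) sleep and wake
  time; at bedtime the resident walks home along the shortest room path, so
  consecutive occupied rooms are always connected.
* **Emission**: the room's PIR sensor fires on entry and, while the resident
  stays, repeatedly with gaps of 8 s (the hardware cool-down) plus an
  exponential waiting time — a renewal process whose rate is the
  "re-trigger" rate.  Emitted gaps therefore can never violate the
  cool-down.  An ``entry_only`` mode (re-trigger rate 0) is available since
  real PIR hardware may or may not re-fire under sustained presence.
* **Activity change** is injected by scaling both the movement rate (dwell
  times shrink) and the re-trigger rate by ``max(0, 1 + slope * day)``.
  The percent-of-baseline statistic responds linearly to such uniform rate
  scaling, so a participant simulated with activity slope ``s`` should be
  recovered with a pd slope of about ``-s`` (activity down = pd up).
* **Nuisance structure**: per-participant log-normal baseline rate
  heterogeneity, absence spells (vacation / short-term care /
  hospitalization) that silence whole days, and visitor noise — spurious
  events in random rooms that may form physically impossible transitions,
  exactly the contamination that impossible-transition masking absorbs.

Every generator is deterministic given its seed and returns ground truth
(injected slopes, absence calendars, visitor event indices, true daily
counts) so recovery tests can compare against the construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import date as Date, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ContentError, ParameterError
from .events import (
    PIR_COOLDOWN_SECONDS,
    AssessmentRecord,
    EventLog,
    FlatTopology,
    write_assessments,
    write_event_log,
    write_topology,
)
from .preprocess import AbsenceInterval, ParticipantStatus, write_status

ROOM_NAMES = ("bedroom", "bathroom", "kitchen", "living room", "hallway")

#: Dwell-time means in minutes by room role; unknown rooms fall back to 15.
_DWELL_MEAN_MINUTES = {
    "bedroom": 25.0,
    "bathroom": 10.0,
    "kitchen": 18.0,
    "living room": 40.0,
    "hallway": 3.0,
}
_DWELL_LOG_SD = 0.6
_ABSENCE_REASONS = ("vacation", "short-term care", "hospitalization")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_topology(n_rooms: int = 5, seed=0) -> FlatTopology:
    """A connected flat with a hallway hub and one PIR sensor per room.

    The hallway connects to every other room; extra direct connections are
    added at random, except bedroom-bathroom, which stays indirect (via the
    hallway) — so for four or more rooms at least one room pair is never
    directly reachable.  One room receives a second, redundant sensor.
    Deterministic for a given seed.
    """
    if n_rooms < 1:
        raise ParameterError(f"n_rooms {n_rooms} must be >= 1")
    rng = _rng(seed)
    rooms = list(ROOM_NAMES[:n_rooms])
    rooms += [f"room{i}" for i in range(len(rooms), n_rooms)]
    hub = "hallway" if "hallway" in rooms else rooms[0]
    connections = [(hub, r) for r in rooms if r != hub]
    for i, a in enumerate(rooms):
        for b in rooms[i + 1 :]:
            if hub in (a, b):
                continue
            if {a, b} == {"bedroom", "bathroom"}:
                continue  # the flats' canonical indirect pair
            if rng.random() < 0.35:
                connections.append((a, b))
    sensor_map = {f"pir-{room.replace(' ', '-')}": room for room in rooms}
    redundant_room = rooms[int(rng.integers(len(rooms)))]
    sensor_map[f"pir-{redundant_room.replace(' ', '-')}-b"] = redundant_room
    return FlatTopology.from_connections(rooms, sensor_map, connections)


@dataclass
class ResidentModel:
    """Movement and emission parameters of a lone resident.

    ``transition_probs`` is row-stochastic with zero probability on
    transitions the topology forbids; rates are in events per minute of
    presence and are scaled, together with the movement rate, by the daily
    activity factor.
    """

    topology: FlatTopology
    transition_probs: np.ndarray
    dwell_log_mean: np.ndarray  # log of minutes, per room
    dwell_log_sd: np.ndarray
    retrigger_rate: float = 0.5  # events/min while present, daytime
    night_rate: float = 0.04  # events/min while asleep (turning in bed)
    sleep_room: str = "bedroom"
    sleep_start_hour: float = 22.5
    wake_hour: float = 6.5
    schedule_jitter_hour: float = 0.5
    emission_mode: str = "retrigger"  # or "entry_only"

    def __post_init__(self) -> None:
        n = self.topology.n
        self.transition_probs = np.asarray(self.transition_probs, dtype=float)
        if self.transition_probs.shape != (n, n):
            raise ContentError("transition matrix shape does not match rooms")
        if np.any(self.transition_probs < 0):
            raise ContentError("transition probabilities must be nonnegative")
        if not np.allclose(self.transition_probs.sum(axis=1), 1.0):
            raise ContentError("transition rows must sum to 1")
        forbidden = ~self.topology.transition_mask()
        if np.any(self.transition_probs[forbidden] > 0):
            raise ContentError("positive probability on an impossible transition")
        if self.retrigger_rate < 0 or self.night_rate < 0:
            raise ContentError("rates must be >= 0")
        if self.emission_mode not in ("retrigger", "entry_only"):
            raise ContentError(f"unknown emission mode {self.emission_mode!r}")
        if self.sleep_room not in self.topology.rooms:
            raise ContentError(f"sleep room {self.sleep_room!r} not in topology")

    @classmethod
    def default_for(
        cls,
        topology: FlatTopology,
        retrigger_rate: float = 0.5,
        emission_mode: str = "retrigger",
    ) -> "ResidentModel":
        """Uniform-over-neighbors movement with room-typical dwell times."""
        n = topology.n
        index = topology.room_index()
        probs = np.zeros((n, n))
        for room in topology.rooms:
            i = index[room]
            nbrs = [index[r] for r in topology.neighbors(room)]
            if nbrs:
                probs[i, nbrs] = 1.0 / len(nbrs)
            else:
                probs[i, i] = 1.0  # isolated room: the resident stays put
        dwell_mean = np.array(
            [_DWELL_MEAN_MINUTES.get(r, 15.0) for r in topology.rooms]
        )
        sleep_room = "bedroom" if "bedroom" in topology.rooms else topology.rooms[0]
        return cls(
            topology=topology,
            transition_probs=probs,
            dwell_log_mean=np.log(dwell_mean),
            dwell_log_sd=np.full(n, _DWELL_LOG_SD),
            retrigger_rate=retrigger_rate,
            sleep_room=sleep_room,
            emission_mode=emission_mode,
        )


@dataclass
class ParticipantGroundTruth:
    """What was injected into one participant's stream."""

    participant_id: str
    group: str
    activity_slope: float
    rate_multiplier: float
    expected_pd_slope: float
    absence_dates: tuple
    daily_event_counts: dict
    visitor_event_count: int = 0


@dataclass
class CohortGroundTruth:
    participants: dict
    group_activity_slopes: dict
    expected_pd_slopes: dict


def _renewal_times(t0: float, t1: float, rate_per_min: float, rng) -> np.ndarray:
    """Sensor re-fire times in (t0, t1): gaps of cool-down + Exp(1/rate)."""
    if rate_per_min <= 0:
        return np.empty(0)
    mean_gap = PIR_COOLDOWN_SECONDS + 60.0 / rate_per_min
    span = t1 - t0
    if span <= mean_gap * 0.01:
        return np.empty(0)
    est = max(int(span / mean_gap * 1.5) + 5, 8)
    gaps = PIR_COOLDOWN_SECONDS + rng.exponential(60.0 / rate_per_min, size=est)
    times = t0 + np.cumsum(gaps)
    while times[-1] < t1:
        extra = PIR_COOLDOWN_SECONDS + rng.exponential(60.0 / rate_per_min, size=est)
        times = np.concatenate([times, times[-1] + np.cumsum(extra)])
    return times[times < t1]


def _simulate_day(
    model: ResidentModel,
    factor: float,
    rng,
    cum_probs: np.ndarray,
    successors: list,
    home_paths: dict,
) -> tuple[np.ndarray, np.ndarray]:
    """One day of (event second, room index) pairs, chronological."""
    index = model.topology.room_index()
    sleep_idx = index[model.sleep_room]
    wake = float(
        np.clip(model.wake_hour + rng.normal(0, model.schedule_jitter_hour), 4.0, 10.5)
    ) * 3600.0
    bedtime = float(
        np.clip(
            model.sleep_start_hour + rng.normal(0, model.schedule_jitter_hour),
            19.0,
            23.8,
        )
    ) * 3600.0
    retrig = (
        model.retrigger_rate * factor if model.emission_mode == "retrigger" else 0.0
    )
    night = model.night_rate * factor

    times: list[np.ndarray] = []
    rooms: list[np.ndarray] = []

    def emit_block(block_times: np.ndarray, room: int) -> None:
        if len(block_times):
            times.append(block_times)
            rooms.append(np.full(len(block_times), room, dtype=np.int64))

    def emit_one(t: float, room: int) -> None:
        times.append(np.array([t]))
        rooms.append(np.array([room], dtype=np.int64))

    # asleep from midnight to wake
    emit_block(_renewal_times(0.0, wake, night, rng), sleep_idx)

    # daytime semi-Markov walk; movement rate scales with the activity factor
    t, room = wake, sleep_idx
    move_factor = max(factor, 1e-6)
    while t < bedtime:
        dwell = float(
            np.exp(model.dwell_log_mean[room] + model.dwell_log_sd[room] * rng.normal())
        ) * 60.0 / move_factor
        # a room cannot be left and re-entered faster than the cool-down
        dwell = float(np.clip(dwell, PIR_COOLDOWN_SECONDS, 4 * 3600.0))
        end = min(t + dwell, bedtime)
        emit_block(_renewal_times(t, end, retrig, rng), room)
        t = end
        if t >= bedtime:
            break
        succ = successors[room]
        if len(succ) == 0 or (len(succ) == 1 and succ[0] == room):
            continue  # nowhere to go; dwell again
        nxt = int(succ[np.searchsorted(cum_probs[room], rng.random())])
        if nxt == room:
            continue
        emit_one(t, nxt)
        room = nxt

    # walk home along the shortest path, then sleep
    if room != sleep_idx:
        for hop in home_paths[room][1:]:
            t += float(rng.uniform(20.0, 60.0))
            if t >= 86400.0:
                break
            emit_one(t, hop)
            room = hop
    if room == sleep_idx and t < 86400.0:
        emit_block(_renewal_times(t, 86400.0, night, rng), sleep_idx)

    if not times:
        return np.empty(0), np.empty(0, dtype=np.int64)
    all_t = np.concatenate(times)
    all_r = np.concatenate(rooms)
    order = np.argsort(all_t, kind="stable")
    return all_t[order], all_r[order]


def _movement_tables(model: ResidentModel):
    """Precompute successor lists, cumulative rows and shortest paths home."""
    n = model.topology.n
    index = model.topology.room_index()
    successors, cum_probs = [], []
    for i in range(n):
        row = model.transition_probs[i]
        succ = np.flatnonzero(row > 0)
        successors.append(succ)
        p = row[succ]
        cum_probs.append(np.cumsum(p) / p.sum() if len(p) else np.empty(0))
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for a, b in model.topology.possible_transitions:
        if a != b:
            G.add_edge(index[a], index[b])
    sleep_idx = index[model.sleep_room]
    home_paths = {}
    for i in range(n):
        try:
            home_paths[i] = nx.shortest_path(G, i, sleep_idx)
        except nx.NetworkXNoPath:
            home_paths[i] = [i]
    return successors, cum_probs, home_paths


def simulate_participant(
    model: ResidentModel,
    *,
    days: int,
    seed=0,
    participant_id: str = "p01",
    group: str = "intervention",
    start_date: Date = Date(2015, 1, 1),
    activity_slope: float = 0.0,
    rate_multiplier: float = 1.0,
    absence_dates: Sequence[Date] = (),
) -> tuple[EventLog, ParticipantGroundTruth]:
    """Simulate one participant's event log over ``days`` civil days.

    The day-``d`` activity factor is ``rate_multiplier * max(0, 1 +
    activity_slope * d)`` and scales movement and re-trigger rates alike.
    Absence days emit nothing.  Timestamps are whole seconds (UTC); the
    integer rounding cannot shrink a >= 8 s gap below 8 s, so emitted logs
    always satisfy the cool-down.
    """
    if days < 1:
        raise ParameterError(f"days {days} must be >= 1")
    rng = _rng(seed)
    successors, cum_probs, home_paths = _movement_tables(model)
    absent = set(absence_dates)

    day_seconds: list[np.ndarray] = []
    day_rooms: list[np.ndarray] = []
    daily_counts: dict[str, int] = {}
    for d in range(days):
        date = start_date + timedelta(days=d)
        if date in absent:
            daily_counts[date.isoformat()] = 0
            continue
        factor = rate_multiplier * max(0.0, 1.0 + activity_slope * d)
        t, r = _simulate_day(model, factor, rng, cum_probs, successors, home_paths)
        daily_counts[date.isoformat()] = len(t)
        if len(t):
            day_seconds.append(np.round(t).astype(np.int64) + d * 86400)
            day_rooms.append(r)

    primary_sensor: dict[int, str] = {}
    index = model.topology.room_index()
    for sensor, room in model.topology.sensor_map.items():
        primary_sensor.setdefault(index[room], sensor)

    if day_seconds:
        seconds = np.concatenate(day_seconds)
        rooms = np.concatenate(day_rooms)
        base = pd.Timestamp(start_date, tz="UTC").value // 10**9
        stamps = pd.to_datetime(seconds + base, unit="s", utc=True)
        sensors = np.array([primary_sensor[i] for i in range(model.topology.n)])[rooms]
        frame = pd.DataFrame({"timestamp": stamps, "sensor_id": sensors})
    else:
        frame = pd.DataFrame(
            {
                "timestamp": pd.Series([], dtype="datetime64[ns, UTC]"),
                "sensor_id": pd.Series([], dtype=str),
            }
        )
    log = EventLog(participant_id, frame)
    truth = ParticipantGroundTruth(
        participant_id=participant_id,
        group=group,
        activity_slope=float(activity_slope),
        rate_multiplier=float(rate_multiplier),
        expected_pd_slope=float(-activity_slope),
        absence_dates=tuple(sorted(absent)),
        daily_event_counts=daily_counts,
    )
    return log, truth


def inject_visitor_noise(
    log: EventLog,
    topology: FlatTopology,
    rate_per_day: float,
    seed=0,
) -> tuple[EventLog, np.ndarray]:
    """Add spurious sensor events from other people in the flat.

    Events are placed uniformly over the log's date span in uniformly chosen
    sensors, so some of them create physically impossible transition pairs.
    The hardware cool-down still binds: injected events that would put two
    firings of one sensor closer than 8 s are discarded rather than emitted.
    Returns the contaminated log and the row positions of the injected
    events in it.
    """
    if rate_per_day < 0:
        raise ParameterError("rate must be >= 0")
    rng = _rng(seed)
    if rate_per_day == 0 or len(log) == 0:
        return EventLog(log.participant_id, log.frame.copy()), np.empty(0, dtype=int)

    ts = log.frame["timestamp"]
    start = ts.iloc[0].normalize()
    span_days = int((ts.iloc[-1].normalize() - start).days) + 1
    n_inject = int(rng.poisson(rate_per_day * span_days))
    if n_inject == 0:
        return EventLog(log.participant_id, log.frame.copy()), np.empty(0, dtype=int)

    sensors = np.array(sorted(topology.sensor_map))
    inj_seconds = np.sort(rng.integers(0, span_days * 86400, size=n_inject))
    inj_stamps = start + pd.to_timedelta(inj_seconds, unit="s")
    inj_frame = pd.DataFrame(
        {
            "timestamp": inj_stamps,
            "sensor_id": sensors[rng.integers(0, len(sensors), size=n_inject)],
        }
    )
    merged = pd.concat(
        [log.frame.assign(_injected=False), inj_frame.assign(_injected=True)]
    ).sort_values("timestamp", kind="mergesort")
    merged = merged.reset_index(drop=True)

    # enforce the per-sensor cool-down by dropping offending *injected* rows
    while True:
        sec = merged["timestamp"].astype("int64").to_numpy() / 1e9
        codes = pd.factorize(merged["sensor_id"])[0]
        injected = merged["_injected"].to_numpy()
        drop: set[int] = set()
        order = np.lexsort((sec, codes))
        same = codes[order][1:] == codes[order][:-1]
        close = (sec[order][1:] - sec[order][:-1]) < PIR_COOLDOWN_SECONDS
        for prev, cur in zip(order[:-1][same & close], order[1:][same & close]):
            if injected[cur]:
                drop.add(int(cur))
            elif injected[prev]:
                drop.add(int(prev))
        if not drop:
            break
        merged = merged.drop(index=list(drop)).reset_index(drop=True)

    indices = np.flatnonzero(merged["_injected"].to_numpy())
    out = EventLog(
        log.participant_id, merged.drop(columns="_injected").reset_index(drop=True)
    )
    return out, indices


@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort.

    Defaults reflect a ten-month single-resident observational study:
    nine intervention participants with an approximately flat activity
    trend, six controls declining by 0.1 % of their activity per day,
    311 civil days (one baseline week plus about ten months of follow-up),
    around seven to eight absent days per participant, and a trickle of
    visitor events.  Slopes are fractional activity change per day.
    """

    n_intervention: int = 9
    n_control: int = 6
    intervention_slope: float = -0.0001
    control_slope: float = -0.001
    study_days: int = 311
    n_rooms: int = 5
    retrigger_rate: float = 0.5
    rate_multiplier_sigma: float = 0.35
    absence_spell_mean: float = 1.5  # expected spells per participant
    absence_day_mean: float = 5.0  # expected days per spell
    visitor_rate_per_day: float = 1.0
    start_date: Date = Date(2015, 1, 1)
    assessment_interval_days: int = 31
    intervention_sppb_change: float = 0.16  # points over the study
    control_sppb_change: float = 0.06
    intervention_tug_change: float = -0.10  # seconds over the study
    control_tug_change: float = -0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_intervention < 0 or self.n_control < 0:
            raise ParameterError("group sizes must be >= 0")
        if self.study_days < 1:
            raise ParameterError("study length must be >= 1 day")


@dataclass
class SyntheticCohort:
    """Everything the pipeline consumes, plus the construction's ground truth."""

    logs: dict
    topologies: dict
    statuses: dict
    assessments: list
    ground_truth: CohortGroundTruth

    @property
    def participant_ids(self) -> list[str]:
        return list(self.logs)

    def to_directory(self, path) -> None:
        """Write the dataset in the package's CSV/JSON dialects."""
        root = Path(path)
        (root / "events").mkdir(parents=True, exist_ok=True)
        (root / "topologies").mkdir(exist_ok=True)
        (root / "statuses").mkdir(exist_ok=True)
        for pid in self.participant_ids:
            write_event_log(self.logs[pid], root / "events" / f"{pid}.csv")
            write_topology(self.topologies[pid], root / "topologies" / f"{pid}.json")
            write_status(self.statuses[pid], root / "statuses" / f"{pid}.json")
        write_assessments(self.assessments, root / "assessments.csv")
        truth = {
            "group_activity_slopes": self.ground_truth.group_activity_slopes,
            "expected_pd_slopes": self.ground_truth.expected_pd_slopes,
            "participants": {
                pid: {
                    "group": t.group,
                    "activity_slope": t.activity_slope,
                    "rate_multiplier": t.rate_multiplier,
                    "expected_pd_slope": t.expected_pd_slope,
                    "absence_dates": [d.isoformat() for d in t.absence_dates],
                    "visitor_event_count": t.visitor_event_count,
                }
                for pid, t in self.ground_truth.participants.items()
            },
        }
        with open(root / "ground_truth.json", "w", encoding="utf-8") as fh:
            json.dump(truth, fh, indent=2)


def _absence_calendar(rng, spec: CohortSpec) -> list[AbsenceInterval]:
    """Non-overlapping absence spells within the study window."""
    n_spells = int(rng.poisson(spec.absence_spell_mean))
    intervals: list[AbsenceInterval] = []
    taken: set[int] = set()
    for _ in range(n_spells):
        length = 1 + int(rng.poisson(max(spec.absence_day_mean - 1.0, 0.0)))
        latest = spec.study_days - length
        if latest <= 8:
            continue
        start_day = int(rng.integers(8, latest))
        days = set(range(start_day, start_day + length))
        if days & taken:
            continue
        taken |= days
        start = spec.start_date + timedelta(days=start_day)
        intervals.append(
            AbsenceInterval(
                start=start,
                end=start + timedelta(days=length - 1),
                reason=_ABSENCE_REASONS[int(rng.integers(len(_ABSENCE_REASONS)))],
            )
        )
    return sorted(intervals, key=lambda iv: iv.start)


def _simulate_assessments(
    rng, pid: str, group: str, spec: CohortSpec
) -> list[AssessmentRecord]:
    sppb_change = (
        spec.intervention_sppb_change if group == "intervention" else spec.control_sppb_change
    )
    tug_change = (
        spec.intervention_tug_change if group == "intervention" else spec.control_tug_change
    )
    sppb0 = float(np.clip(np.round(rng.normal(6.5, 2.3)), 1, 11))
    tug0 = float(np.clip(rng.normal(16.8, 4.3), 9.0, 30.0))
    records = []
    day = 0
    while day < spec.study_days:
        sppb = int(np.clip(np.round(
            sppb0 + sppb_change * day / spec.study_days + rng.normal(0, 0.7)
        ), 0, 12))
        tug = float(max(
            1.0, tug0 + tug_change * day / spec.study_days + rng.normal(0, 0.8)
        ))
        records.append(
            AssessmentRecord(
                participant_id=pid,
                date=spec.start_date + timedelta(days=day),
                sppb=sppb,
                tug=round(tug, 2),
            )
        )
        day += spec.assessment_interval_days + int(rng.integers(-3, 4))
    return records


def simulate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a full cohort dataset, deterministic for ``spec.seed``.

    Each participant gets an independent child random stream, their own flat
    topology, a log-normal baseline activity multiplier, an absence
    calendar, the group's injected activity slope, visitor contamination,
    and monthly assessments drifting by the group's configured SPPB/TUG
    change.
    """
    n_total = spec.n_intervention + spec.n_control
    children = np.random.SeedSequence(spec.seed).spawn(max(n_total, 1))
    logs, topologies, statuses = {}, {}, {}
    assessments: list[AssessmentRecord] = []
    truths: dict[str, ParticipantGroundTruth] = {}

    for i in range(n_total):
        pid = f"p{i + 1:02d}"
        group = "intervention" if i < spec.n_intervention else "control"
        slope = (
            spec.intervention_slope if group == "intervention" else spec.control_slope
        )
        rng = np.random.default_rng(children[i])
        topology = generate_topology(spec.n_rooms, rng)
        model = ResidentModel.default_for(topology, retrigger_rate=spec.retrigger_rate)
        rate_multiplier = float(np.exp(rng.normal(0.0, spec.rate_multiplier_sigma)))
        absences = _absence_calendar(rng, spec)
        absence_dates = [
            iv.start + timedelta(days=k)
            for iv in absences
            for k in range(iv.n_days)
        ]
        log, truth = simulate_participant(
            model,
            days=spec.study_days,
            seed=rng,
            participant_id=pid,
            group=group,
            start_date=spec.start_date,
            activity_slope=slope,
            rate_multiplier=rate_multiplier,
            absence_dates=absence_dates,
        )
        if spec.visitor_rate_per_day > 0:
            log, injected = inject_visitor_noise(
                log, topology, spec.visitor_rate_per_day, rng
            )
            truth.visitor_event_count = len(injected)
        logs[pid] = log
        topologies[pid] = topology
        statuses[pid] = ParticipantStatus(
            participant_id=pid, group=group, absences=tuple(absences)
        )
        assessments.extend(_simulate_assessments(rng, pid, group, spec))
        truths[pid] = truth

    ground_truth = CohortGroundTruth(
        participants=truths,
        group_activity_slopes={
            "intervention": spec.intervention_slope,
            "control": spec.control_slope,
        },
        expected_pd_slopes={
            "intervention": -spec.intervention_slope,
            "control": -spec.control_slope,
        },
    )
    return SyntheticCohort(
        logs=logs,
        topologies=topologies,
        statuses=statuses,
        assessments=assessments,
        ground_truth=ground_truth,
    )
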