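"""Shared fixtures: small topologies and programmatic event-log builders."""

from datetime import date as Date

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from sensorgraphs.events import DayEvents, EventLog, FlatTopology
from sensorgraphs.examples import five_room_example

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def triangle_topology() -> FlatTopology:
    """Three fully connected rooms, one sensor each."""
    rooms = ("a", "b", "c")
    return FlatTopology.from_connections(
        rooms,
        {f"pir-{r}": r for r in rooms},
        [("a", "b"), ("b", "c"), ("a", "c")],
    )


@pytest.fixture
def example():
    return five_room_example()


def primary_sensor(topology: FlatTopology, room: str) -> str:
    for sensor, mapped in topology.sensor_map.items():
        if mapped == room:
            return sensor
    raise KeyError(room)


def day_from_rooms(
    topology: FlatTopology,
    rooms,
    date: Date = Date(2015, 3, 1),
    spacing_s: int = 30,
    participant_id: str = "p01",
) -> DayEvents:
    """A DayEvents visiting ``rooms`` in order, events ``spacing_s`` apart."""
    base = pd.Timestamp(date, tz="UTC")
    frame = pd.DataFrame(
        {
            "timestamp": [base + pd.Timedelta(seconds=i * spacing_s) for i in range(len(rooms))],
            "sensor_id": [primary_sensor(topology, r) for r in rooms],
        }
    )
    if not len(rooms):
        frame = pd.DataFrame(
            {
                "timestamp": pd.Series([], dtype="datetime64[ns, UTC]"),
                "sensor_id": pd.Series([], dtype=str),
            }
        )
    return DayEvents(participant_id, date, frame)


def log_from_offsets(
    offsets_s,
    sensors,
    participant_id: str = "p01",
    start: str = "2015-03-01T00:00:00+00:00",
) -> EventLog:
    """An EventLog with events at the given second offsets from ``start``."""
    base = pd.Timestamp(start)
    frame = pd.DataFrame(
        {
            "timestamp": [base + pd.Timedelta(seconds=float(o)) for o in offsets_s],
            "sensor_id": list(sensors),
        }
    )
    if not len(frame):
        frame = pd.DataFrame(
            {
                "timestamp": pd.Series([], dtype="datetime64[ns, UTC]"),
                "sensor_id": pd.Series([], dtype=str),
            }
        )
    return EventLog(participant_id, frame)


def pair_tally(room_indices, n: int) -> np.ndarray:
    """Brute-force consecutive-pair tally; the independent construction oracle."""
    M = np.zeros((n, n))
    for a, b in zip(room_indices, room_indices[1:]):
        M[a, b] += 1
    return M
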