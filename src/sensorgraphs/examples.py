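"""Bundled reference example: one five-room flat.

A small worked example used throughout the documentation and tests: the
one-week baseline adjacency matrix and a single day's adjacency matrix of a
five-room flat (bedroom, bathroom, kitchen, living room, hallway).  In this
flat the bathroom can only be reached through the hallway, so the direct
bedroom-bathroom and kitchen-bathroom transitions are physically impossible
and carry weight 0 in both matrices.

With the default weight matrix (1 on the diagonal, 1.5 off it) the example
evaluates to diff(B, D) = -21.10 and pd = -21.10 / 1115.90 = -1.89 % — the
day was slightly *more* active than the baseline week.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .difference import BaselineMatrix
from .events import FlatTopology
from .graphs import AdjacencyMatrix

EXAMPLE_ROOMS = ("Bedroom", "Bathroom", "Kitchen", "Living room", "Hallway")

_BASELINE = np.array(
    [
        [45.14, 0.00, 0.14, 34.84, 1.86],
        [0.00, 114.29, 0.00, 1.00, 22.86],
        [0.00, 0.00, 144.86, 38.14, 0.43],
        [35.14, 1.29, 38.43, 294.43, 50.71],
        [1.71, 19.57, 0.14, 51.86, 70.00],
    ]
)

_DAY = np.array(
    [
        [45.0, 0.0, 0.0, 34.0, 1.0],
        [0.0, 98.0, 0.0, 1.0, 25.0],
        [0.0, 0.0, 196.0, 39.0, 1.0],
        [32.0, 1.0, 39.0, 230.0, 68.0],
        [3.0, 25.0, 1.0, 66.0, 64.0],
    ]
)


@dataclass(frozen=True)
class ExampleFlat:
    """The bundled five-room example: baseline, one day, and the topology."""

    baseline: BaselineMatrix
    day: AdjacencyMatrix
    topology: FlatTopology


def five_room_example() -> ExampleFlat:
    """Return the bundled five-room worked example (fresh copies)."""
    rooms = EXAMPLE_ROOMS
    sensor_map = {f"pir-{r.lower().replace(' ', '-')}": r for r in rooms}
    connections = [
        ("Bedroom", "Kitchen"),
        ("Bedroom", "Living room"),
        ("Bedroom", "Hallway"),
        ("Bathroom", "Living room"),
        ("Bathroom", "Hallway"),
        ("Kitchen", "Living room"),
        ("Kitchen", "Hallway"),
        ("Living room", "Hallway"),
    ]
    topology = FlatTopology.from_connections(rooms, sensor_map, connections)
    baseline = BaselineMatrix(
        AdjacencyMatrix(rooms, _BASELINE.copy()), dates=(), window=7
    )
    return ExampleFlat(
        baseline=baseline,
        day=AdjacencyMatrix(rooms, _DAY.copy()),
        topology=topology,
    )
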