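"""Daily room-transition graphs and their adjacency matrices.

A day of sensor events is turned into a weighted directed multigraph over the
flat's rooms: every consecutive pair of events adds 1 to the edge from the
first event's room to the second's, so motion inside one room accumulates on
the diagonal (loops) and room changes accumulate off it.  Transitions that
are physically impossible in the flat (no direct path between the two rooms)
are forced to weight 0 — they can only arise from a second person in the
flat or a glitching sensor, never from the resident.

The adjacency matrix is the working representation; a NetworkX ``DiGraph``
view is available for graph-library interoperability.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ContentError, FormatError
from .events import DayEvents, FlatTopology


@dataclass(eq=False)
class AdjacencyMatrix:
    """A labeled nonnegative n x n transition-count matrix.

    Row = source room, column = destination room; label order is fixed by
    the flat topology so matrices of the same flat are directly comparable.
    """

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ContentError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if np.any(self.values < 0):
            raise ContentError("adjacency weights must be nonnegative")

    @classmethod
    def zeros(cls, labels) -> "AdjacencyMatrix":
        labels = tuple(labels)
        return cls(labels, np.zeros((len(labels), len(labels))))

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def total(self) -> float:
        """Sum of all edge weights (total recorded transition mass)."""
        return float(self.values.sum())

    def loc(self, src: str, dst: str) -> float:
        i = self.labels.index(src)
        j = self.labels.index(dst)
        return float(self.values[i, j])

    def copy(self) -> "AdjacencyMatrix":
        return AdjacencyMatrix(self.labels, self.values.copy())

    def equals(self, other: "AdjacencyMatrix") -> bool:
        return self.labels == other.labels and np.array_equal(
            self.values, other.values
        )

    def allclose(self, other: "AdjacencyMatrix", **kwargs) -> bool:
        return self.labels == other.labels and np.allclose(
            self.values, other.values, **kwargs
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AdjacencyMatrix":
        if list(frame.index) != list(frame.columns):
            raise FormatError("row and column labels differ")
        return cls(tuple(frame.index), frame.to_numpy(dtype=float))


def apply_edge_update(G: AdjacencyMatrix, i: int, j: int) -> AdjacencyMatrix:
    """Add one observed transition from room ``i`` to room ``j``.

    This is the elementary weight update: the result equals ``G`` plus the
    single-entry matrix with a 1 at ``(i, j)``.  Returns a new matrix.
    """
    n = G.n
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"edge ({i}, {j}) out of range for {n} rooms")
    out = G.copy()
    out.values[i, j] += 1.0
    return out


def build_daily_matrix(
    day: DayEvents,
    topology: FlatTopology,
    *,
    mask: bool = True,
) -> AdjacencyMatrix:
    """Tally one day's events into an adjacency matrix.

    Sensor ids are mapped to rooms through the topology (several sensors in
    one room collapse onto one vertex).  Each consecutive event pair adds 1
    to its ordered room pair, so an unmasked day of m >= 1 events has total
    weight m - 1.  With ``mask=True`` (default) impossible transitions are
    zeroed afterwards.
    """
    index = topology.room_index()
    M = np.zeros((topology.n, topology.n))
    sensors = day.sensor_ids
    if len(sensors):
        unknown = [s for s in pd.unique(sensors) if s not in topology.sensor_map]
        if unknown:
            raise ContentError(f"sensors not in topology: {sorted(unknown)}")
        rooms = np.array([index[topology.sensor_map[s]] for s in sensors])
        np.add.at(M, (rooms[:-1], rooms[1:]), 1.0)
    A = AdjacencyMatrix(topology.rooms, M)
    if mask:
        A, _ = mask_impossible(A, topology)
    return A


def mask_impossible(
    A: AdjacencyMatrix, topology: FlatTopology
) -> tuple[AdjacencyMatrix, float]:
    """Zero the weights of physically impossible transitions.

    Returns the masked matrix and the total weight removed.  Masking is
    idempotent and never re-routes the removed mass to other edges.
    """
    if A.labels != topology.rooms:
        raise ContentError(
            f"matrix labels {A.labels} do not match topology rooms {topology.rooms}"
        )
    allowed = topology.transition_mask()
    removed = float(A.values[~allowed].sum())
    out = A.copy()
    out.values[~allowed] = 0.0
    return out, removed


def read_adjacency(path) -> AdjacencyMatrix:
    """Read a room-labeled adjacency CSV (first row/column are labels)."""
    frame = pd.read_csv(path, index_col=0)
    if frame.shape[0] != frame.shape[1]:
        raise FormatError(f"{path}: matrix is {frame.shape}, not square")
    frame.columns = [str(c) for c in frame.columns]
    frame.index = [str(i) for i in frame.index]
    return AdjacencyMatrix.from_frame(frame)


def write_adjacency(A: AdjacencyMatrix, path) -> None:
    """Write a labeled adjacency CSV; values round-trip exactly."""
    A.to_frame().to_csv(path)


def to_networkx(A: AdjacencyMatrix, topology: FlatTopology | None = None) -> nx.DiGraph:
    """Directed-graph view with one weighted edge per nonzero ordered pair.

    Edge weights are the transition counts, so the multigraph's parallel
    edges are represented by integer weights.  Zero-weight pairs are kept as
    edges only when ``topology`` marks them possible, mirroring the incident
    function's codomain.
    """
    G = nx.DiGraph()
    G.add_nodes_from(A.labels)
    for i, src in enumerate(A.labels):
        for j, dst in enumerate(A.labels):
            w = A.values[i, j]
            if w > 0 or (topology is not None and topology.is_possible(src, dst)):
                G.add_edge(src, dst, weight=float(w))
    return G


def from_networkx(G: nx.DiGraph, labels) -> AdjacencyMatrix:
    """Inverse of :func:`to_networkx` for a given room order."""
    A = AdjacencyMatrix.zeros(labels)
    index = {room: i for i, room in enumerate(A.labels)}
    for src, dst, data in G.edges(data=True):
        A.values[index[src], index[dst]] = float(data.get("weight", 0.0))
    return A
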