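"""Cognitive-map landmark hierarchy, the four insertion scenarios, and
hierarchical (primary-then-detailed) route selection.

The spatial content of a training scenario is a small graph of landmarks.
Primary landmarks are decision points of the insertion path: ``A`` (start,
sacral hiatus), ``B`` (dorsal-to-ventral detour point, absent in scenarios 3
and 4) and ``C`` (destination, the lesion disc).  Secondary landmarks are the
sacral nerves ``S1``-``S4``, used as reference points for detailed path
selection.  Route selection is hierarchical: a coarse primary-landmark
sequence is fixed first, then each leg between consecutive primary landmarks
is solved independently on the full graph (divide and conquer).
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    IncompleteEnvironmentError,
    InvalidScenarioError,
    ScenarioFormatError,
    UnroutableError,
)

PRIMARY_IDS = ("A", "B", "C")
SECONDARY_IDS = ("S1", "S2", "S3", "S4")
LANDMARK_IDS = PRIMARY_IDS + SECONDARY_IDS

SCENARIO_IDS = (1, 2, 3, 4, "free")

#: Landmark sequences per scenario id.  Scenario 1's sequences are fixed by
#: the design (A -> S4 -> S3 -> B -> S2 -> S1 -> C); scenarios 2 and 4 mirror
#: 1 and 3 with the destination disc one level lower.  Overridable via the
#: ``sequences`` argument of :func:`build_scenario`.
DEFAULT_SEQUENCES: dict[int, tuple[list[str], list[str]]] = {
    1: (["A", "B", "C"], ["A", "S4", "S3", "B", "S2", "S1", "C"]),
    2: (["A", "B", "C"], ["A", "S4", "S3", "B", "S2", "C"]),
    3: (["A", "C"], ["A", "S4", "S3", "S2", "S1", "C"]),
    4: (["A", "C"], ["A", "S3", "S2", "C"]),
}


@dataclass(eq=False)
class Landmark:
    """A named point of the cognitive map.

    Parameters
    ----------
    id : str
        One of ``A``, ``B``, ``C``, ``S1``..``S4``.
    level : str
        ``"primary"`` for A/B/C, ``"secondary"`` for S1-S4.
    role : str
        ``"start"`` (A), ``"detour"`` (B), ``"destination"`` (C) or
        ``"reference"`` (S1-S4).
    position : (3,) ndarray
        Position in mm.
    """

    id: str
    level: str
    role: str
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ScenarioFormatError(
                f"landmark {self.id!r}: position must be a 3-vector"
            )
        if self.id in PRIMARY_IDS and self.level != "primary":
            raise ScenarioFormatError(f"landmark {self.id!r}: must be primary")
        if self.id in SECONDARY_IDS and self.level != "secondary":
            raise ScenarioFormatError(f"landmark {self.id!r}: must be secondary")

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "level": self.level,
            "role": self.role,
            "position_mm": [float(x) for x in self.position],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Landmark":
        for key in ("id", "level", "role", "position_mm"):
            if key not in d:
                raise ScenarioFormatError(f"landmark record: missing field {key!r}")
        return cls(d["id"], d["level"], d["role"], np.asarray(d["position_mm"]))


class CognitiveMapGraph:
    """Landmark graph whose edges carry ordered waypoint chains (mm).

    Each edge chain starts at the source landmark position and ends at the
    target landmark position; chains are traversable in either direction.
    """

    def __init__(
        self,
        nodes: Iterable[Landmark],
        edges: Iterable[tuple[str, str, np.ndarray]],
        *,
        tol: float = 1e-9,
    ) -> None:
        self.nodes: dict[str, Landmark] = {lm.id: lm for lm in nodes}
        self._chains: dict[tuple[str, str], np.ndarray] = {}
        for src, dst, chain in edges:
            if src not in self.nodes or dst not in self.nodes:
                raise ScenarioFormatError(f"edge ({src}, {dst}): unknown landmark id")
            chain = np.asarray(chain, dtype=float)
            if chain.ndim != 2 or chain.shape[1] != 3 or chain.shape[0] < 2:
                raise ScenarioFormatError(
                    f"edge ({src}, {dst}): chain must be an (n>=2, 3) array"
                )
            if np.linalg.norm(chain[0] - self.nodes[src].position) > tol:
                raise ScenarioFormatError(
                    f"edge ({src}, {dst}): chain does not start at {src}"
                )
            if np.linalg.norm(chain[-1] - self.nodes[dst].position) > tol:
                raise ScenarioFormatError(
                    f"edge ({src}, {dst}): chain does not end at {dst}"
                )
            self._chains[(src, dst)] = chain
        if self.nodes and not self._connected():
            raise ScenarioFormatError("cognitive-map graph is not connected")

    def _connected(self) -> bool:
        if not self._chains:
            return len(self.nodes) <= 1
        seen: set[str] = set()
        stack = [next(iter(self.nodes))]
        while stack:
            nid = stack.pop()
            if nid in seen:
                continue
            seen.add(nid)
            stack.extend(n for n in self.neighbors(nid) if n not in seen)
        return seen == set(self.nodes)

    def neighbors(self, nid: str) -> list[str]:
        out = []
        for (s, d) in self._chains:
            if s == nid:
                out.append(d)
            elif d == nid:
                out.append(s)
        return sorted(set(out))

    def has_edge(self, src: str, dst: str) -> bool:
        return (src, dst) in self._chains or (dst, src) in self._chains

    def chain(self, src: str, dst: str) -> np.ndarray:
        """Waypoint chain oriented from *src* to *dst*."""
        if (src, dst) in self._chains:
            return self._chains[(src, dst)].copy()
        if (dst, src) in self._chains:
            return self._chains[(dst, src)][::-1].copy()
        raise UnroutableError(f"no edge between {src!r} and {dst!r}")

    def edge_length(self, src: str, dst: str) -> float:
        c = self.chain(src, dst)
        return float(np.linalg.norm(np.diff(c, axis=0), axis=1).sum())

    def edge_list(self) -> list[tuple[str, str]]:
        return sorted(self._chains)

    def to_dict(self) -> dict:
        return {
            "nodes": [self.nodes[k].to_dict() for k in sorted(self.nodes)],
            "edges": [
                {
                    "source": s,
                    "target": d,
                    "waypoints_mm": [[float(x) for x in p] for p in self._chains[(s, d)]],
                }
                for s, d in sorted(self._chains)
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CognitiveMapGraph":
        for key in ("nodes", "edges"):
            if key not in d:
                raise ScenarioFormatError(f"graph record: missing field {key!r}")
        nodes = [Landmark.from_dict(n) for n in d["nodes"]]
        edges = []
        for e in d["edges"]:
            for key in ("source", "target", "waypoints_mm"):
                if key not in e:
                    raise ScenarioFormatError(f"graph edge: missing field {key!r}")
            edges.append((e["source"], e["target"], np.asarray(e["waypoints_mm"])))
        return cls(nodes, edges)


def _leg_shortest(graph: CognitiveMapGraph, start: str, dest: str) -> list[str]:
    """Shortest landmark path minimizing (chain length, node count, id order).

    Dijkstra with a lexicographic cost tuple; all components are additive and
    non-negative, so the first pop of a node is optimal.
    """
    if start == dest:
        return [start]
    heap: list[tuple[float, int, tuple[str, ...]]] = [(0.0, 1, (start,))]
    done: set[str] = set()
    while heap:
        cost, nnodes, path = heapq.heappop(heap)
        node = path[-1]
        if node == dest:
            return list(path)
        if node in done:
            continue
        done.add(node)
        for nb in graph.neighbors(node):
            if nb in done:
                continue
            heapq.heappush(
                heap,
                (cost + graph.edge_length(node, nb), nnodes + 1, path + (nb,)),
            )
    raise UnroutableError(f"no path from {start!r} to {dest!r}")


def hierarchical_route(
    graph: CognitiveMapGraph,
    start: str,
    dest: str,
    primary_hops: Sequence[str],
) -> list[str]:
    """Divide-and-conquer route: solve each primary-landmark leg independently.

    ``primary_hops`` must begin with *start* and end with *dest*.  Returns the
    concatenated per-leg shortest paths with duplicated junction nodes
    removed.
    """
    if not primary_hops or primary_hops[0] != start or primary_hops[-1] != dest:
        raise ValueError("primary_hops must begin with start and end with dest")
    for nid in primary_hops:
        if nid not in graph.nodes:
            raise UnroutableError(f"landmark {nid!r} not in graph")
    route: list[str] = [start]
    for a, b in zip(primary_hops[:-1], primary_hops[1:]):
        leg = _leg_shortest(graph, a, b)
        route.extend(leg[1:])
    return route


@dataclass(eq=False)
class Scenario:
    """A training scenario: landmark sequences, centerline and tube radius.

    The free scenario has an empty centerline and no tube
    (``tube_radius is None``).
    """

    id: int | str
    primary_sequence: list[str]
    detailed_sequence: list[str]
    centerline: np.ndarray
    tube_radius: float | None
    side_profile: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.id not in SCENARIO_IDS:
            raise InvalidScenarioError(f"unknown scenario id {self.id!r}")
        self.centerline = np.asarray(self.centerline, dtype=float).reshape(-1, 3)
        if self.id in (1, 2) and "B" not in self.primary_sequence:
            raise ScenarioFormatError(
                f"scenario {self.id}: primary_sequence must contain B"
            )
        if self.id in (3, 4) and "B" in self.primary_sequence:
            raise ScenarioFormatError(
                f"scenario {self.id}: primary_sequence must not contain B"
            )
        seq = self.detailed_sequence
        if not seq or seq[0] != "A" or seq[-1] != "C":
            raise ScenarioFormatError(
                f"scenario {self.id}: detailed_sequence must begin with A and end with C"
            )
        if self.id == "free":
            if len(self.centerline) != 0 or self.tube_radius is not None:
                raise ScenarioFormatError(
                    "free scenario must have empty centerline and no tube"
                )
        else:
            if len(self.centerline) < 2:
                raise ScenarioFormatError(
                    f"scenario {self.id}: centerline needs at least 2 points"
                )
            if np.any(np.all(np.diff(self.centerline, axis=0) == 0.0, axis=1)):
                raise ScenarioFormatError(
                    f"scenario {self.id}: consecutive centerline points must differ"
                )
            if self.tube_radius is None or self.tube_radius <= 0:
                raise ScenarioFormatError(
                    f"scenario {self.id}: tube_radius must be positive"
                )

    @property
    def is_free(self) -> bool:
        return self.id == "free"

    def centerline_length(self) -> float:
        if len(self.centerline) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.centerline, axis=0), axis=1).sum())

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "tube_radius_mm": None if self.tube_radius is None else float(self.tube_radius),
            "primary_sequence": list(self.primary_sequence),
            "detailed_sequence": list(self.detailed_sequence),
            "centerline_mm": [[float(x) for x in p] for p in self.centerline],
            "side_profile": list(self.side_profile),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        for key in (
            "id",
            "tube_radius_mm",
            "primary_sequence",
            "detailed_sequence",
            "centerline_mm",
            "side_profile",
        ):
            if key not in d:
                raise ScenarioFormatError(f"scenario record: missing field {key!r}")
        return cls(
            id=d["id"],
            primary_sequence=list(d["primary_sequence"]),
            detailed_sequence=list(d["detailed_sequence"]),
            centerline=np.asarray(d["centerline_mm"], dtype=float).reshape(-1, 3),
            tube_radius=d["tube_radius_mm"],
            side_profile=list(d["side_profile"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))


def load_scenario(path: str | Path) -> Scenario:
    try:
        d = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ScenarioFormatError(f"{path}: invalid JSON at line {exc.lineno}") from exc
    if not isinstance(d, dict):
        raise ScenarioFormatError(f"{path}: top-level value must be an object")
    return Scenario.from_dict(d)


def build_scenario(sid, env, sequences: dict | None = None) -> Scenario:
    """Assemble a Scenario from a generated environment.

    The centerline is threaded through the detailed landmark sequence using
    the environment's waypoint chains.  ``sequences`` may override
    :data:`DEFAULT_SEQUENCES`.
    """
    if sid not in SCENARIO_IDS:
        raise InvalidScenarioError(f"unknown scenario id {sid!r}")
    missing = [lid for lid in LANDMARK_IDS if env.landmark(lid) is None]
    if missing:
        raise IncompleteEnvironmentError(f"environment lacks landmarks: {missing}")
    if sid == "free":
        return Scenario(
            id="free",
            primary_sequence=["A", "C"],
            detailed_sequence=["A", "C"],
            centerline=np.empty((0, 3)),
            tube_radius=None,
            side_profile=[],
        )
    table = dict(DEFAULT_SEQUENCES)
    if sequences:
        table.update(sequences)
    primary, detailed = table[sid]
    pts: list[np.ndarray] = []
    for a, b in zip(detailed[:-1], detailed[1:]):
        if not env.graph.has_edge(a, b):
            raise IncompleteEnvironmentError(
                f"environment lacks the waypoint chain {a} - {b}"
            )
        chain = env.graph.chain(a, b)
        pts.extend(chain if not pts else chain[1:])
    centerline = np.asarray(pts)
    keep = np.r_[True, np.linalg.norm(np.diff(centerline, axis=0), axis=1) > 1e-12]
    centerline = centerline[keep]
    if "B" in detailed:
        b_at = detailed.index("B")
        side = ["dorsal"] * b_at + ["ventral"] * (len(detailed) - 1 - b_at)
    else:
        side = ["ventral"] * (len(detailed) - 1)
    return Scenario(
        id=sid,
        primary_sequence=list(primary),
        detailed_sequence=list(detailed),
        centerline=centerline,
        tube_radius=float(env.params.tube_radius),
        side_profile=side,
    )
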