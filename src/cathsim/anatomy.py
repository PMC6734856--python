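"""Procedural synthetic epidural-space environment.

Generates landmark positions, dorsal/ventral waypoint chains and analytic
organ collision primitives (capsules, spheres, boxes) standing in for a
hand-modeled 3D scene.  Coordinate convention: right-handed, millimetres,
+z from the sacral hiatus toward the head, +y dorsal.  All dimensions are
synthetic defaults, not anatomical ground truth, and every one is
overridable through :class:`AnatomyParams`.

Layout: the dura is a capsule on the canal axis.  Landmarks sit on a
coaxial corridor cylinder of radius ``path_offset``: A (start) at the caudal
end at angle 0, the sacral nerves S4..S1 laterally (angle 0) in anatomical
order along +z, B (the dorsal-to-ventral detour point) dorsally (+y) between
S3 and S2, and C (destination) ventrally (-y) at the cranial end.  Backbone
waypoint chains hug the corridor; alternate "skip" chains swing to a wider
radius so that the backbone is always the shortest detailed route.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .errors import InvalidParameterError, ScenarioFormatError, UnsupportedShapeError
from .scenario import CognitiveMapGraph, Landmark

ORGAN_KINDS = ("bone", "dura", "disc", "nerve")
ORGAN_SHAPES = ("sphere", "capsule", "box")


@dataclass
class AnatomyParams:
    """Geometry parameters (mm) of the synthetic environment."""

    canal_length: float = 200.0
    dura_radius: float = 8.0
    tube_radius: float = 3.0
    nerve_radius: float = 2.0
    path_offset: float = 9.5        # radial distance of the waypoint corridor
    skip_extra_radius: float = 10.0  # extra radius of alternate-route chains
    nerve_clearance: float = 3.0     # corridor -> nerve-capsule axis gap
    nerve_length: float = 12.0
    disc_radius: float = 5.0
    jitter: float = 1.5              # landmark spacing jitter along the canal

    def validate(self) -> None:
        for name in (
            "canal_length",
            "dura_radius",
            "tube_radius",
            "nerve_radius",
            "path_offset",
            "skip_extra_radius",
            "nerve_clearance",
            "nerve_length",
            "disc_radius",
        ):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if self.jitter < 0:
            raise InvalidParameterError("jitter must be non-negative")
        if self.jitter > 0.05 * self.canal_length:
            raise InvalidParameterError("jitter too large for landmark ordering")
        if self.path_offset <= self.dura_radius:
            raise InvalidParameterError("path_offset must exceed dura_radius")


@dataclass(eq=False)
class OrganPrimitive:
    """Analytic collision primitive with an exact signed distance.

    ``parameters`` per shape:
      sphere  -- {"center_mm": [x,y,z], "radius_mm": r}
      capsule -- {"p0_mm": [..], "p1_mm": [..], "radius_mm": r}
      box     -- {"center_mm": [..], "half_extents_mm": [hx,hy,hz]}
                 (axis-aligned)
    """

    kind: str
    shape: str
    parameters: dict
    label: str

    def __post_init__(self) -> None:
        if self.kind not in ORGAN_KINDS:
            raise ScenarioFormatError(f"organ {self.label!r}: unknown kind {self.kind!r}")
        if self.shape == "sphere":
            if self.parameters["radius_mm"] <= 0:
                raise InvalidParameterError(f"organ {self.label!r}: radius must be positive")
        elif self.shape == "capsule":
            if self.parameters["radius_mm"] <= 0:
                raise InvalidParameterError(f"organ {self.label!r}: radius must be positive")
        elif self.shape == "box":
            if np.any(np.asarray(self.parameters["half_extents_mm"]) <= 0):
                raise InvalidParameterError(
                    f"organ {self.label!r}: half-extents must be positive"
                )
        else:
            raise UnsupportedShapeError(f"organ {self.label!r}: shape {self.shape!r}")

    def to_dict(self) -> dict:
        params = {
            k: ([float(x) for x in v] if isinstance(v, (list, tuple, np.ndarray)) else float(v))
            for k, v in self.parameters.items()
        }
        return {"kind": self.kind, "shape": self.shape, "parameters": params, "label": self.label}

    @classmethod
    def from_dict(cls, d: dict) -> "OrganPrimitive":
        for key in ("kind", "shape", "parameters", "label"):
            if key not in d:
                raise ScenarioFormatError(f"organ record: missing field {key!r}")
        return cls(d["kind"], d["shape"], dict(d["parameters"]), d["label"])


def organ_distance(point, organ: OrganPrimitive) -> float:
    """Exact signed distance (mm): negative inside, zero on the surface."""
    p = np.asarray(point, dtype=float)
    prm = organ.parameters
    if organ.shape == "sphere":
        c = np.asarray(prm["center_mm"], dtype=float)
        return float(np.linalg.norm(p - c) - prm["radius_mm"])
    if organ.shape == "capsule":
        a = np.asarray(prm["p0_mm"], dtype=float)
        b = np.asarray(prm["p1_mm"], dtype=float)
        d = b - a
        denom = float(d @ d)
        t = 0.0 if denom == 0.0 else float(np.clip((p - a) @ d / denom, 0.0, 1.0))
        return float(np.linalg.norm(p - (a + t * d)) - prm["radius_mm"])
    if organ.shape == "box":
        c = np.asarray(prm["center_mm"], dtype=float)
        h = np.asarray(prm["half_extents_mm"], dtype=float)
        q = np.abs(p - c) - h
        outside = float(np.linalg.norm(np.maximum(q, 0.0)))
        inside = float(min(np.max(q), 0.0))
        return outside + inside
    raise UnsupportedShapeError(f"shape {organ.shape!r}")


class OrganSet:
    """Vectorized nearest-organ signed-distance queries over a primitive list.

    Groups primitives by shape so a containment query is three batched
    computations instead of a Python loop; exact same distances as
    :func:`organ_distance`.
    """

    def __init__(self, organs) -> None:
        self.organs = list(organs)
        self.labels = [o.label for o in self.organs]
        cap, box = [], []
        for i, o in enumerate(self.organs):
            p = o.parameters
            if o.shape == "sphere":  # zero-length capsule
                cap.append((i, p["center_mm"], p["center_mm"], p["radius_mm"]))
            elif o.shape == "capsule":
                cap.append((i, p["p0_mm"], p["p1_mm"], p["radius_mm"]))
            elif o.shape == "box":
                box.append((i, p["center_mm"], p["half_extents_mm"]))
            else:
                raise UnsupportedShapeError(f"shape {o.shape!r}")
        self._cap_i = [i for i, *_ in cap]
        self._cap_a = np.array([a for _, a, _, _ in cap], dtype=float).reshape(-1, 3)
        cap_b = np.array([b for _, _, b, _ in cap], dtype=float).reshape(-1, 3)
        self._cap_d = cap_b - self._cap_a
        self._cap_len2 = np.maximum(np.einsum("ij,ij->i", self._cap_d, self._cap_d), 1e-300)
        self._cap_r = np.array([r for _, _, _, r in cap], dtype=float)
        self._box_i = [i for i, *_ in box]
        self._box_c = np.array([c for _, c, _ in box], dtype=float).reshape(-1, 3)
        self._box_h = np.array([h for _, _, h in box], dtype=float).reshape(-1, 3)
        self._order = self._cap_i + self._box_i

    def _block_distances(self, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        rel = p - self._cap_a
        t = np.einsum("ij,ij->i", rel, self._cap_d) / self._cap_len2
        t = np.minimum(np.maximum(t, 0.0), 1.0)
        q = rel - t[:, None] * self._cap_d
        d_cap = np.sqrt(np.einsum("ij,ij->i", q, q)) - self._cap_r
        q = np.abs(p - self._box_c) - self._box_h
        qp = np.maximum(q, 0.0)
        d_box = np.sqrt(np.einsum("ij,ij->i", qp, qp)) + np.minimum(np.max(q, axis=1), 0.0)
        return d_cap, d_box

    def signed_distances(self, point) -> np.ndarray:
        """Signed distances in the original organ order."""
        p = np.asarray(point, dtype=float)
        d_cap, d_box = self._block_distances(p)
        out = np.empty(len(self.organs))
        out[self._order] = np.concatenate([d_cap, d_box])
        return out

    def query(self, point) -> tuple[float, str]:
        """(minimum signed distance, label of the nearest organ).

        Hot path of free-mode containment: per-shape block minima, no
        concatenation or reordering.
        """
        p = np.asarray(point, dtype=float)
        d_cap, d_box = self._block_distances(p)
        best = np.inf
        best_i = 0
        if d_cap.size:
            j = int(d_cap.argmin())
            if d_cap[j] < best:
                best, best_i = float(d_cap[j]), self._cap_i[j]
        if d_box.size:
            j = int(d_box.argmin())
            if d_box[j] < best:
                best, best_i = float(d_box[j]), self._box_i[j]
        return best, self.labels[best_i]

    def __iter__(self):
        return iter(self.organs)

    def __len__(self) -> int:
        return len(self.organs)


@dataclass(eq=False)
class Environment:
    """Generated scene: landmarks, waypoint-chain graph, organs and bounds."""

    landmarks: list[Landmark]
    graph: CognitiveMapGraph
    organs: list[OrganPrimitive]
    bounds: np.ndarray  # (2, 3): min corner, max corner
    seed: int
    params: AnatomyParams

    def __post_init__(self) -> None:
        self.bounds = np.asarray(self.bounds, dtype=float).reshape(2, 3)
        for lm in self.landmarks:
            if np.any(lm.position < self.bounds[0]) or np.any(lm.position > self.bounds[1]):
                raise InvalidParameterError(f"landmark {lm.id!r} outside bounds")

    def landmark(self, lid: str) -> Landmark | None:
        for lm in self.landmarks:
            if lm.id == lid:
                return lm
        return None

    def to_dict(self) -> dict:
        return {
            "seed": int(self.seed),
            "params": {k: float(v) for k, v in asdict(self.params).items()},
            "bounds_mm": [[float(x) for x in row] for row in self.bounds],
            "landmarks": [lm.to_dict() for lm in self.landmarks],
            "graph": self.graph.to_dict(),
            "organs": [o.to_dict() for o in self.organs],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_dict(cls, d: dict) -> "Environment":
        for key in ("seed", "params", "bounds_mm", "landmarks", "graph", "organs"):
            if key not in d:
                raise ScenarioFormatError(f"environment record: missing field {key!r}")
        return cls(
            landmarks=[Landmark.from_dict(x) for x in d["landmarks"]],
            graph=CognitiveMapGraph.from_dict(d["graph"]),
            organs=[OrganPrimitive.from_dict(x) for x in d["organs"]],
            bounds=np.asarray(d["bounds_mm"], dtype=float),
            seed=int(d["seed"]),
            params=AnatomyParams(**d["params"]),
        )


def load_environment(path: str | Path) -> Environment:
    try:
        d = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ScenarioFormatError(f"{path}: invalid JSON at line {exc.lineno}") from exc
    return Environment.from_dict(d)


def _on_corridor(radius: float, angle: float, z: float) -> np.ndarray:
    return np.array([radius * np.cos(angle), radius * np.sin(angle), z])


def generate_environment(seed: int, params: AnatomyParams | None = None) -> Environment:
    """Generate a synthetic environment; bit-identical for identical inputs."""
    params = params or AnatomyParams()
    params.validate()
    rng = np.random.default_rng(seed)
    L = params.canal_length
    r = params.path_offset

    # Nerve landmarks in anatomical order along +z: S4 caudal .. S1 cranial.
    base = np.array([0.2, 0.4, 0.6, 0.8]) * L
    z_nerves = base + rng.uniform(-params.jitter, params.jitter, 4)
    zS4, zS3, zS2, zS1 = z_nerves
    zB = 0.5 * (zS3 + zS2)

    angles = {"A": 0.0, "S4": 0.0, "S3": 0.0, "S2": 0.0, "S1": 0.0,
              "B": np.pi / 2, "C": -np.pi / 2}
    zs = {"A": 0.0, "S4": zS4, "S3": zS3, "B": zB, "S2": zS2, "S1": zS1, "C": L}
    pos = {k: _on_corridor(r, angles[k], zs[k]) for k in zs}

    landmarks = [
        Landmark("A", "primary", "start", pos["A"]),
        Landmark("B", "primary", "detour", pos["B"]),
        Landmark("C", "primary", "destination", pos["C"]),
        Landmark("S1", "secondary", "reference", pos["S1"]),
        Landmark("S2", "secondary", "reference", pos["S2"]),
        Landmark("S3", "secondary", "reference", pos["S3"]),
        Landmark("S4", "secondary", "reference", pos["S4"]),
    ]

    def chain(a: str, b: str, mid_radius: float) -> np.ndarray:
        mid = _on_corridor(
            mid_radius, 0.5 * (angles[a] + angles[b]), 0.5 * (zs[a] + zs[b])
        )
        return np.vstack([pos[a], mid, pos[b]])

    backbone = [("A", "S4"), ("S4", "S3"), ("S3", "B"), ("B", "S2"),
                ("S2", "S1"), ("S1", "C")]
    skips = [("A", "S3"), ("S3", "S2"), ("S2", "C")]
    edges = [(a, b, chain(a, b, r)) for a, b in backbone]
    edges += [(a, b, chain(a, b, r + params.skip_extra_radius)) for a, b in skips]
    graph = CognitiveMapGraph(landmarks, edges)

    nerve_x0 = r + params.nerve_clearance
    organs = [
        OrganPrimitive(
            "dura", "capsule",
            {"p0_mm": [0.0, 0.0, 0.05 * L], "p1_mm": [0.0, 0.0, 0.95 * L],
             "radius_mm": params.dura_radius},
            "dura",
        ),
        OrganPrimitive(
            "disc", "sphere",
            {"center_mm": [0.0, -r, L + params.disc_radius + 3.0],
             "radius_mm": params.disc_radius},
            "lesion-disc",
        ),
    ]
    for lid, z in (("S1", zS1), ("S2", zS2), ("S3", zS3), ("S4", zS4)):
        organs.append(
            OrganPrimitive(
                "nerve", "capsule",
                {"p0_mm": [nerve_x0, 0.0, z],
                 "p1_mm": [nerve_x0 + params.nerve_length, 0.0, z],
                 "radius_mm": params.nerve_radius},
                lid,
            )
        )
    wall = r + params.skip_extra_radius + 4.0  # clear of the widest skip chain
    organs += [
        OrganPrimitive(
            "bone", "box",
            {"center_mm": [0.0, wall + 4.0, 0.5 * L],
             "half_extents_mm": [20.0, 4.0, 0.55 * L]},
            "lamina-dorsal",
        ),
        OrganPrimitive(
            "bone", "box",
            {"center_mm": [0.0, -(wall + 4.0), 0.5 * L],
             "half_extents_mm": [20.0, 4.0, 0.55 * L]},
            "vertebral-body-ventral",
        ),
        OrganPrimitive(
            "bone", "box",
            {"center_mm": [-(wall + 6.0), 0.0, 5.0],
             "half_extents_mm": [6.0, 14.0, 12.0]},
            "sacrum",
        ),
    ]

    margin = wall + 10.0
    bounds = np.array([[-margin, -margin, -15.0], [margin, margin, L + 20.0]])
    return Environment(
        landmarks=landmarks, graph=graph, organs=organs,
        bounds=bounds, seed=int(seed), params=params,
    )
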