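"""Tube virtual fixture: arc-length centerline queries, containment,
excursion collision detection, and the guidance penalty force.

Collision semantics: one :class:`CollisionEvent` per excursion, i.e. per
inside -> outside transition of the containment signal sampled at the
simulator steps.  A per-timestep counting mode is available behind the
``per_step`` flag of :func:`detect_collision` for sensitivity checks.
Beyond the first/last centerline vertex the distance is taken to the
terminal vertex (capped tube ends).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .anatomy import OrganPrimitive, OrganSet, organ_distance
from .errors import InvalidParameterError, MisconfiguredModeError


class TubeFixture:
    """Arc-length-parameterized tube around a polyline centerline.

    Parameters
    ----------
    centerline : (n, 3) array
        Ordered centerline vertices, mm, with n >= 2 and consecutive
        vertices distinct.
    radius : float
        Tube radius, mm, > 0.
    """

    def __init__(self, centerline, radius: float) -> None:
        c = np.asarray(centerline, dtype=float)
        if c.ndim != 2 or c.shape[1] != 3 or c.shape[0] < 2:
            raise InvalidParameterError("centerline must be an (n>=2, 3) array")
        if radius <= 0:
            raise InvalidParameterError("radius must be positive")
        seg = np.diff(c, axis=0)
        seglen = np.linalg.norm(seg, axis=1)
        if np.any(seglen == 0.0):
            raise InvalidParameterError("consecutive centerline points must differ")
        self.centerline = c
        self.radius = float(radius)
        self._seg = seg
        self._seglen = seglen
        self._seglen2 = seglen**2
        self.cumulative_arclength = np.concatenate([[0.0], np.cumsum(seglen)])

    @property
    def length(self) -> float:
        return float(self.cumulative_arclength[-1])

    def query(self, point) -> tuple[float, float, int, np.ndarray]:
        """(distance, arclength, segment_index, nearest point) for *point*.

        Exact minimum over all segments; ties resolve to the smaller
        segment index.
        """
        p = np.asarray(point, dtype=float)
        rel = p - self.centerline[:-1]
        t = np.einsum("ij,ij->i", rel, self._seg) / self._seglen2
        np.clip(t, 0.0, 1.0, out=t)
        proj = self.centerline[:-1] + t[:, None] * self._seg
        d2 = np.einsum("ij,ij->i", p - proj, p - proj)
        i = int(np.argmin(d2))
        s = float(self.cumulative_arclength[i] + t[i] * self._seglen[i])
        return float(np.sqrt(d2[i])), s, i, proj[i]

    def point_at_arclength(self, s: float) -> np.ndarray:
        """Centerline point at arc length *s* (clamped to [0, length])."""
        s = float(np.clip(s, 0.0, self.length))
        i = int(np.searchsorted(self.cumulative_arclength, s, side="right") - 1)
        i = min(i, len(self._seglen) - 1)
        t = (s - self.cumulative_arclength[i]) / self._seglen[i]
        return self.centerline[i] + t * self._seg[i]


def distance_to_centerline(point, fixture: TubeFixture) -> tuple[float, float, int]:
    """Minimum distance from *point* to the centerline polyline.

    Returns ``(distance_mm, arclength_mm, segment_index)``; the arclength
    locates the nearest centerline point.
    """
    d, s, i, _ = fixture.query(point)
    return d, s, i


def fixture_force(point, fixture: TubeFixture, stiffness: float) -> np.ndarray:
    """Penalty-spring guidance force (N): zero inside the tube, outside
    ``stiffness * penetration`` directed from the tip toward its nearest
    centerline point."""
    if stiffness < 0:
        raise InvalidParameterError("stiffness must be non-negative")
    p = np.asarray(point, dtype=float)
    d, _, _, nearest = fixture.query(p)
    if d <= fixture.radius or d == 0.0:
        return np.zeros(3)
    direction = (nearest - p) / d
    return stiffness * (d - fixture.radius) * direction


@dataclass(eq=False)
class CollisionEvent:
    """One recorded excursion start (or organ contact in free mode)."""

    time: float
    position: np.ndarray
    penetration: float
    source: str  # "fixture" | "organ"
    segment_index: Optional[int] = None
    organ_label: Optional[str] = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.penetration <= 0:
            raise InvalidParameterError("penetration must be positive")
        if self.source == "fixture" and self.segment_index is None:
            raise InvalidParameterError("fixture event needs a segment index")

    def to_dict(self) -> dict:
        return {
            "t": float(self.time),
            "type": "collision",
            "source": self.source,
            "pos_mm": [float(x) for x in self.position],
            "penetration_mm": float(self.penetration),
            "segment": None if self.segment_index is None else int(self.segment_index),
            "organ": self.organ_label,
        }


def containment(
    point,
    fixture: TubeFixture | None = None,
    organs: Sequence[OrganPrimitive] | None = None,
) -> tuple[bool, float, Optional[int], Optional[str]]:
    """Containment test for a tip position.

    Fixture mode: inside iff centerline distance <= radius.  Free mode:
    inside (free space) iff outside every organ.  Returns
    ``(inside, penetration, segment_index, organ_label)`` where penetration
    is > 0 only when outside/in contact.
    """
    if fixture is not None:
        d, _, i, _ = fixture.query(point)
        pen = d - fixture.radius
        return pen <= 0.0, max(pen, 0.0), i, None
    if organs is not None:
        if isinstance(organs, OrganSet):
            sd, label = organs.query(point)
        else:
            sds = [organ_distance(point, o) for o in organs]
            j = int(np.argmin(sds))
            sd, label = sds[j], organs[j].label
        inside_free = sd >= 0.0  # boundary contact is not yet a collision
        return inside_free, max(-sd, 0.0), None, label
    raise MisconfiguredModeError("supply a fixture or organs")


def detect_collision(
    prev,
    next,
    fixture: TubeFixture | None = None,
    organs: Sequence[OrganPrimitive] | None = None,
    t: float | None = None,
    *,
    per_step: bool = False,
) -> Optional[CollisionEvent]:
    """Emit a collision event on an inside -> outside transition.

    *prev* and *next* are consecutive catheter states (objects with ``tip``
    and ``inside`` attributes).  Exactly one event is produced per contiguous
    excursion across calls; with ``per_step=True`` an event is produced for
    every step spent outside instead.
    """
    if fixture is None and organs is None:
        raise MisconfiguredModeError("supply a fixture or organs")
    inside_next, pen, seg, label = containment(next.tip, fixture, organs)
    crossed = prev.inside and not inside_next
    if not (crossed or (per_step and not inside_next)):
        return None
    return CollisionEvent(
        time=float(next.t if t is None else t),
        position=np.asarray(next.tip, dtype=float).copy(),
        penetration=pen,
        source="fixture" if fixture is not None else "organ",
        segment_index=seg,
        organ_label=label,
    )


def write_events_jsonl(events: Iterable[CollisionEvent], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ev in events:
            fh.write(json.dumps(ev.to_dict(), sort_keys=True) + "\n")


def read_events_jsonl(path: str | Path) -> list[dict]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(json.loads(line))
    return out
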