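"""Orthographic fluoroscopy-like projection of the scene onto a raster.

The survey-map 2D view: organs are drawn as silhouettes at kind-specific
gray levels (bone brightest), with the scenario centerline, landmark
markers and the catheter tip overlaid.  Output is 8-bit PGM (P5) for
dependency-free bit-exact comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .anatomy import Environment, OrganPrimitive
from .errors import InvalidParameterError, UnsupportedShapeError
from .scenario import Scenario

VIEW_AXES = ("lateral", "anteroposterior")

#: Silhouette gray levels; bone is brightest.
ORGAN_GRAY = {"bone": 220, "disc": 150, "nerve": 120, "dura": 80}
CENTERLINE_GRAY = 180
MARKER_GRAY = 255
BACKGROUND_GRAY = 0


@dataclass
class ProjectionSpec:
    """Orthographic projection onto an image plane.

    ``view_axis='lateral'`` projects along +x (image axes: row from y, col
    from z); ``'anteroposterior'`` projects along +y (row from x, col from
    z).  ``origin`` is the world-mm point mapped to pixel (0, 0).
    """

    view_axis: str = "lateral"
    pixel_spacing: float = 0.5  # mm / px
    image_size: tuple[int, int] = (160, 480)  # (width, height) px
    origin: tuple[float, float] = (-40.0, -15.0)  # (row_mm, col_mm)

    def __post_init__(self) -> None:
        if self.view_axis not in VIEW_AXES:
            raise InvalidParameterError(f"unknown view axis {self.view_axis!r}")
        if self.pixel_spacing <= 0:
            raise InvalidParameterError("pixel_spacing must be positive")
        if self.image_size[0] <= 0 or self.image_size[1] <= 0:
            raise InvalidParameterError("image_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) = (height, width)."""
        return (self.image_size[1], self.image_size[0])

    def plane_coords(self, p) -> tuple[float, float]:
        """Continuous (row_mm, col_mm) of a 3D point: drop the view axis."""
        p = np.asarray(p, dtype=float)
        if self.view_axis == "lateral":
            return float(p[1]), float(p[2])
        return float(p[0]), float(p[2])

    def to_dict(self) -> dict:
        return {
            "view_axis": self.view_axis,
            "pixel_spacing_mm": self.pixel_spacing,
            "image_size_px": list(self.image_size),
            "origin_mm": list(self.origin),
        }


def project_point(p, spec: ProjectionSpec) -> Optional[tuple[int, int]]:
    """Map a 3D point (mm) to integer (row, col) pixels, rounding half-up.

    Returns ``None`` for points that fall outside the frame.
    """
    u, v = spec.plane_coords(p)
    row = int(np.floor((u - spec.origin[0]) / spec.pixel_spacing + 0.5))
    col = int(np.floor((v - spec.origin[1]) / spec.pixel_spacing + 0.5))
    rows, cols = spec.shape
    if not (0 <= row < rows and 0 <= col < cols):
        return None
    return row, col


def _silhouette_sdf(organ: OrganPrimitive, spec: ProjectionSpec,
                    U: np.ndarray, V: np.ndarray) -> np.ndarray:
    """2D signed distance of the organ's orthographic silhouette.

    The silhouette of a sphere is a disc, of a capsule a 2D stadium around
    the projected axis, and of an axis-aligned box the projected rectangle.
    """
    prm = organ.parameters
    if organ.shape == "sphere":
        cu, cv = spec.plane_coords(prm["center_mm"])
        return np.hypot(U - cu, V - cv) - prm["radius_mm"]
    if organ.shape == "capsule":
        au, av = spec.plane_coords(prm["p0_mm"])
        bu, bv = spec.plane_coords(prm["p1_mm"])
        du, dv = bu - au, bv - av
        den = du * du + dv * dv
        if den == 0.0:
            return np.hypot(U - au, V - av) - prm["radius_mm"]
        t = np.clip(((U - au) * du + (V - av) * dv) / den, 0.0, 1.0)
        return np.hypot(U - (au + t * du), V - (av + t * dv)) - prm["radius_mm"]
    if organ.shape == "box":
        cu, cv = spec.plane_coords(prm["center_mm"])
        hu, hv = spec.plane_coords(prm["half_extents_mm"])
        qu = np.abs(U - cu) - hu
        qv = np.abs(V - cv) - hv
        outside = np.hypot(np.maximum(qu, 0.0), np.maximum(qv, 0.0))
        inside = np.minimum(np.maximum(qu, qv), 0.0)
        return outside + inside
    raise UnsupportedShapeError(f"shape {organ.shape!r}")


@dataclass(eq=False)
class FluoroImage:
    """8-bit raster plus the projection that produced it."""

    pixels: np.ndarray
    spec: ProjectionSpec

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.shape != self.spec.shape:
            raise InvalidParameterError("pixel grid does not match spec")

    def to_pgm_bytes(self) -> bytes:
        rows, cols = self.pixels.shape
        header = f"P5\n{cols} {rows}\n255\n".encode()
        return header + self.pixels.tobytes()

    def save_pgm(self, path: str | Path) -> None:
        Path(path).write_bytes(self.to_pgm_bytes())


def render_fluoro(
    env: Environment | None,
    scenario: Scenario | None,
    tip=None,
    spec: ProjectionSpec | None = None,
) -> FluoroImage:
    """Deterministic raster of the scene; identical inputs, identical bytes.

    Pixels take the maximum of all overlapping element intensities.  The
    scene objects are never mutated.
    """
    spec = spec or ProjectionSpec()
    rows, cols = spec.shape
    img = np.full((rows, cols), BACKGROUND_GRAY, dtype=np.uint8)

    # pixel-center world coordinates in the projection plane
    U = spec.origin[0] + np.arange(rows)[:, None] * spec.pixel_spacing
    V = spec.origin[1] + np.arange(cols)[None, :] * spec.pixel_spacing
    U = np.broadcast_to(U, (rows, cols))
    V = np.broadcast_to(V, (rows, cols))

    if env is not None:
        for organ in env.organs:
            sdf = _silhouette_sdf(organ, spec, U, V)
            gray = ORGAN_GRAY[organ.kind]
            mask = sdf <= 0.0
            img[mask] = np.maximum(img[mask], gray)

    if scenario is not None and len(scenario.centerline) >= 2:
        seg = np.diff(scenario.centerline, axis=0)
        seglen = np.linalg.norm(seg, axis=1)
        step = 0.25 * spec.pixel_spacing
        for a, d, ln in zip(scenario.centerline[:-1], seg, seglen):
            n = max(int(np.ceil(ln / step)), 1)
            ts = np.linspace(0.0, 1.0, n + 1)
            for p in a + ts[:, None] * d:
                rc = project_point(p, spec)
                if rc is not None:
                    img[rc] = max(img[rc], CENTERLINE_GRAY)

    if env is not None:
        for lm in env.landmarks:
            rc = project_point(lm.position, spec)
            if rc is not None:
                _stamp(img, rc, 1, MARKER_GRAY)

    if tip is not None:
        rc = project_point(tip, spec)
        if rc is not None:
            _stamp(img, rc, 2, MARKER_GRAY)

    return FluoroImage(pixels=img, spec=spec)


def _stamp(img: np.ndarray, rc: tuple[int, int], half: int, gray: int) -> None:
    r0 = max(rc[0] - half, 0)
    r1 = min(rc[0] + half + 1, img.shape[0])
    c0 = max(rc[1] - half, 0)
    c1 = min(rc[1] + half + 1, img.shape[1])
    img[r0:r1, c0:c1] = np.maximum(img[r0:r1, c0:c1], gray)
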