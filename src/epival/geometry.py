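"""Treatment-room coordinate frames and divergent-beam projection geometry.

The room frame is an IEC-style fixed frame with its origin at the linac
isocenter: x is lateral (+ toward patient left for a head-first supine
setup), y is longitudinal (+ superior), z is vertical (+ anterior/up).
The gantry rotates about the y axis; at gantry 0 the source sits directly
above the isocenter at (0, 0, +SAD) and the beam points straight down.

Portal-image positions are expressed in the (u, v) imager frame *at
isocenter scale*: the divergent (pin-hole) projection onto the detector
plane is divided by the magnification SDD/SAD, so that a point in the
plane through the isocenter perpendicular to the beam axis maps to its
in-plane coordinates exactly.  (0, 0) is the beam central axis, u is the
horizontal imager axis and v maps the patient-superior direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "RoomPoint",
    "PanelCoordinate",
    "BeamGeometry",
    "source_position",
    "project_point",
    "project_points",
    "pixel_to_iso_mm",
    "com",
]


@dataclass(frozen=True)
class RoomPoint:
    """A 3D position in the fixed room frame, in mm, origin at isocenter."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in (self.x, self.y, self.z)):
            raise ValueError("RoomPoint components must be finite")

    def __add__(self, other: "RoomPoint") -> "RoomPoint":
        return RoomPoint(self.x + other.x, self.y + other.y, self.z + other.z)

    def __sub__(self, other: "RoomPoint") -> "RoomPoint":
        return RoomPoint(self.x - other.x, self.y - other.y, self.z - other.z)

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(frozen=True)
class PanelCoordinate:
    """A 2D portal-image position in mm at isocenter scale.

    (0, 0) is the beam central axis; u horizontal, v toward patient-superior.
    """

    u: float
    v: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.u) and math.isfinite(self.v)):
            raise ValueError("PanelCoordinate components must be finite")

    def __add__(self, other: "PanelCoordinate") -> "PanelCoordinate":
        return PanelCoordinate(self.u + other.u, self.v + other.v)

    def __sub__(self, other: "PanelCoordinate") -> "PanelCoordinate":
        return PanelCoordinate(self.u - other.u, self.v - other.v)

    def as_array(self) -> np.ndarray:
        return np.array([self.u, self.v], dtype=float)


#: Default source-axis distance, mm (standard C-arm linac).
DEFAULT_SAD_MM = 1000.0
#: Default source-detector distance, mm.
DEFAULT_SDD_MM = 1600.0


@dataclass(frozen=True)
class BeamGeometry:
    """Beam and imaging-panel placement for one treatment field.

    gantry_deg: 0 = source above isocenter, increasing clockwise as seen
    from the foot of the couch.  flex is the rigid mechanical sag of the
    panel, in mm at panel scale, applied in the image domain only.
    """

    gantry_deg: float
    sad: float = DEFAULT_SAD_MM
    sdd: float = DEFAULT_SDD_MM
    flex: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (0.0 < self.sad < self.sdd):
            raise ValueError(f"require 0 < sad < sdd, got sad={self.sad}, sdd={self.sdd}")
        if max(abs(self.flex[0]), abs(self.flex[1])) > 5.0:
            raise ValueError(f"panel flex {self.flex} exceeds the 5 mm physical bound")

    @property
    def magnification(self) -> float:
        """Geometric magnification SDD/SAD of the isocenter plane on the panel."""
        return self.sdd / self.sad

    def beam_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Orthonormal beam-frame axes (e_u, e_v, w) in room coordinates.

        w points from the isocenter toward the source; e_u is the panel
        horizontal axis and e_v the panel vertical (patient-superior) axis.
        """
        g = math.radians(self.gantry_deg)
        w = np.array([math.sin(g), 0.0, math.cos(g)])
        e_u = np.array([math.cos(g), 0.0, -math.sin(g)])
        e_v = np.array([0.0, 1.0, 0.0])
        return e_u, e_v, w


def source_position(geom: BeamGeometry) -> RoomPoint:
    """Room-frame position of the X-ray source for the given gantry angle."""
    _, _, w = geom.beam_axes()
    p = geom.sad * w
    return RoomPoint(p[0], p[1], p[2])


def project_points(points: np.ndarray, geom: BeamGeometry) -> np.ndarray:
    """Project an (n, 3) array of room points to (n, 2) panel (u, v), iso scale.

    Vectorised core of :func:`project_point`; flex is never applied here.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    e_u, e_v, w = geom.beam_axes()
    a = pts @ e_u
    b = pts @ e_v
    c = pts @ w  # signed distance toward the source
    denom = geom.sad - c
    if np.any(denom <= 0):
        raise ValueError("point lies at or behind the source; degenerate ray")
    scale = geom.sad / denom  # divergent magnification already at iso scale
    return np.stack([a * scale, b * scale], axis=-1)


def project_point(p: RoomPoint, geom: BeamGeometry) -> PanelCoordinate:
    """Central projection of a room point onto the imager, mm at isocenter scale.

    The ray from the source through ``p`` is intersected with the detector
    plane and the result divided by the magnification SDD/SAD.  Points in
    the isocenter plane perpendicular to the beam therefore map to their
    in-plane coordinates unchanged.  Panel flex is an image-domain
    perturbation and is deliberately not applied here.
    """
    uv = project_points(p.as_array()[None, :], geom)[0]
    return PanelCoordinate(float(uv[0]), float(uv[1]))


def pixel_to_iso_mm(
    pixels: float, panel_width_mm: float, n_pixels: int, geom: BeamGeometry
) -> float:
    """Convert a pixel count on the panel to mm at isocenter scale."""
    if n_pixels <= 0:
        raise ValueError("n_pixels must be positive")
    return pixels * (panel_width_mm / n_pixels) * (geom.sad / geom.sdd)


def com(points: Sequence[RoomPoint] | Sequence[PanelCoordinate] | Iterable) -> RoomPoint | PanelCoordinate:
    """Center of mass (arithmetic mean per component) of a non-empty point set."""
    pts = list(points)
    if not pts:
        raise ValueError("center of mass of an empty point set is undefined")
    arr = np.array([p.as_array() for p in pts])
    mean = arr.mean(axis=0)
    if isinstance(pts[0], PanelCoordinate):
        return PanelCoordinate(float(mean[0]), float(mean[1]))
    return RoomPoint(float(mean[0]), float(mean[1]), float(mean[2]))
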