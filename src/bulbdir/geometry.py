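"""Detector geometry and the 2D-to-3D direction mapping.

A plant bulb on the conveyor is imaged by three x-ray projection systems
whose detector planes are fanned out at equal angles (60 degrees by
default) around the vertical. Each view yields a 2D growth angle on its
detector plane; pairs of views are triangulated to 3D by intersecting the
two "solution planes" (the plane through a detector spanned by the in-plane
angle vector and the detector normal, which must contain the true 3D growth
direction). The three pairwise 3D estimates are compared by great-circle
distance; if their mean disagreement stays below a threshold tau, their
hemisphere-aligned average is accepted as the final growth direction.

Conventions
-----------
* World frame is right-handed with z pointing up (the planting-relevant
  vertical). Units are mm.
* A detector is described by its plane origin, in-plane unit axes
  ``axis_x`` (columns) and ``axis_y`` (rows), and the unit normal
  ``axis_x x axis_y`` pointing toward the x-ray source.
* 2D angles are measured from ``axis_x`` toward ``axis_y`` and wrapped to
  (-pi, pi].
* 3D directions store a unit vector plus derived elevation ``theta``
  (latitude above the world xy-plane) and azimuth ``phi`` (about world z),
  so the spherical-law-of-cosines distance is exactly the great-circle
  distance between two directions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeometryError",
    "InvalidGeometryError",
    "DegenerateProjectionError",
    "DegenerateTriangulationError",
    "UndefinedMeanError",
    "wrap_angle",
    "Angle2D",
    "DetectorGeometry",
    "Direction3D",
    "EstimateSet",
    "build_detector_ring",
    "rotate_detector",
    "project_direction",
    "angle_to_world_vector",
    "solution_plane_normal",
    "triangulate_pair",
    "angular_distance",
    "mean_direction",
    "aggregate_estimates",
    "DEFAULT_TAU",
]

#: default agreement threshold (40 degrees) applied to the mean pairwise
#: angular distance of the three 3D estimates
DEFAULT_TAU = math.radians(40.0)


class GeometryError(ValueError):
    """Base class for geometry failures."""


class InvalidGeometryError(GeometryError):
    """Detector ring parameters are out of range."""


class DegenerateProjectionError(GeometryError):
    """The 3D direction is (numerically) parallel to the detector normal."""


class DegenerateTriangulationError(GeometryError):
    """The two solution planes coincide; their intersection is not a line."""


class UndefinedMeanError(GeometryError):
    """The hemisphere-aligned mean of the pairwise estimates vanished."""


def wrap_angle(theta: float) -> float:
    """Wrap an angle in radians to the interval (-pi, pi]."""
    return -((math.pi - theta) % (2.0 * math.pi) - math.pi)


def _unit(v: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < eps:
        raise GeometryError("cannot normalize a (near-)zero vector")
    return v / n


@dataclass(frozen=True)
class Angle2D:
    """An in-plane growth angle, wrapped to (-pi, pi] on construction."""

    theta: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "theta", wrap_angle(float(self.theta)))

    def __float__(self) -> float:
        return self.theta


def _as_theta(angle: "Angle2D | float") -> float:
    return wrap_angle(float(angle))


@dataclass(frozen=True)
class DetectorGeometry:
    """One x-ray detector plane in world coordinates (mm).

    ``normal`` is derived as ``axis_x x axis_y`` and points toward the
    x-ray source; rays travel anti-parallel to it.
    """

    origin: np.ndarray
    axis_x: np.ndarray
    axis_y: np.ndarray
    normal: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        origin = np.asarray(self.origin, dtype=float)
        ax = np.asarray(self.axis_x, dtype=float)
        ay = np.asarray(self.axis_y, dtype=float)
        if abs(np.linalg.norm(ax) - 1.0) > 1e-12 or abs(np.linalg.norm(ay) - 1.0) > 1e-12:
            raise InvalidGeometryError("detector axes must be unit vectors")
        if abs(float(ax @ ay)) > 1e-12:
            raise InvalidGeometryError("detector axes must be orthogonal")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "axis_x", ax)
        object.__setattr__(self, "axis_y", ay)
        object.__setattr__(self, "normal", np.cross(ax, ay))


@dataclass(frozen=True)
class Direction3D:
    """A growth direction: unit vector plus elevation/azimuth angles.

    ``theta`` is the elevation (latitude) above the world xy-plane in
    radians, ``phi`` the azimuth about the world z-axis, so that
    ``vec = (cos(theta)cos(phi), cos(theta)sin(phi), sin(theta))``.
    """

    vec: np.ndarray
    theta: float = field(init=False)
    phi: float = field(init=False)

    def __post_init__(self) -> None:
        v = _unit(self.vec)
        object.__setattr__(self, "vec", v)
        object.__setattr__(self, "theta", math.asin(float(np.clip(v[2], -1.0, 1.0))))
        object.__setattr__(self, "phi", math.atan2(v[1], v[0]))

    @classmethod
    def from_angles(cls, theta: float, phi: float) -> "Direction3D":
        ct = math.cos(theta)
        return cls(np.array([ct * math.cos(phi), ct * math.sin(phi), math.sin(theta)]))


@dataclass(frozen=True)
class EstimateSet:
    """The three pairwise 3D estimates with their agreement verdict.

    ``mean_distance`` is the mean pairwise great-circle distance (the
    filter statistic d-bar); ``accepted`` holds iff it is below tau;
    ``mean_direction`` is the hemisphere-aligned normalized mean when
    accepted and ``None`` otherwise.
    """

    pairwise: tuple[Direction3D, Direction3D, Direction3D]
    mean_distance: float
    accepted: bool
    mean_direction: Direction3D | None
    diagnostic: str | None = None


def build_detector_ring(
    separation_deg: float = 60.0,
    distance: float = 200.0,
    azimuth0_deg: float = 0.0,
) -> list[DetectorGeometry]:
    """Build three detector planes fanned out around the vertical.

    The planes sit at equal height with horizontal normals; successive
    normals are separated by ``separation_deg`` degrees. ``distance`` is
    the distance (mm) from the world origin to each detector plane along
    its (inward-pointing) normal. ``axis_y`` is the world vertical for all
    views, so a vertically-growing bulb has an in-plane angle of +90
    degrees in every image.
    """
    if not (0.0 < separation_deg < 180.0):
        raise InvalidGeometryError(
            f"separation must lie in (0, 180) degrees, got {separation_deg}"
        )
    if distance <= 0.0:
        raise InvalidGeometryError(f"distance must be positive, got {distance}")
    detectors = []
    for i in range(3):
        gamma = math.radians(azimuth0_deg + i * separation_deg)
        normal = np.array([math.cos(gamma), math.sin(gamma), 0.0])
        axis_y = np.array([0.0, 0.0, 1.0])
        axis_x = np.array([-math.sin(gamma), math.cos(gamma), 0.0])
        detectors.append(
            DetectorGeometry(origin=-distance * normal, axis_x=axis_x, axis_y=axis_y)
        )
    return detectors


def rotate_detector(det: DetectorGeometry, rotation: np.ndarray) -> DetectorGeometry:
    """Apply a world rotation matrix to a detector plane."""
    rotation = np.asarray(rotation, dtype=float)
    return DetectorGeometry(
        origin=rotation @ det.origin,
        axis_x=rotation @ det.axis_x,
        axis_y=rotation @ det.axis_y,
    )


def project_direction(g: Direction3D, det: DetectorGeometry) -> Angle2D:
    """Orthographic projection of a 3D direction onto a detector plane.

    Returns the in-plane angle measured from ``axis_x`` toward
    ``axis_y``. Raises :class:`DegenerateProjectionError` when the
    direction is (numerically) parallel to the detector normal — the case
    where a view carries no in-plane direction information.
    """
    px = float(g.vec @ det.axis_x)
    py = float(g.vec @ det.axis_y)
    if abs(px) < 1e-9 and abs(py) < 1e-9:
        raise DegenerateProjectionError(
            "direction is parallel to the detector normal; its in-plane "
            "projection is undefined"
        )
    return Angle2D(math.atan2(py, px))


def angle_to_world_vector(theta: "Angle2D | float", det: DetectorGeometry) -> np.ndarray:
    """The unit world vector lying in the detector plane at angle theta."""
    t = _as_theta(theta)
    return math.cos(t) * det.axis_x + math.sin(t) * det.axis_y


def solution_plane_normal(theta: "Angle2D | float", det: DetectorGeometry) -> np.ndarray:
    """Unit normal of the solution plane for one view.

    The solution plane is spanned by the in-plane angle vector and the
    detector normal; the true 3D growth direction must lie in it, i.e. be
    orthogonal to the returned normal.
    """
    v = angle_to_world_vector(theta, det)
    return _unit(np.cross(v, det.normal))


def triangulate_pair(
    theta_i: "Angle2D | float",
    det_i: DetectorGeometry,
    theta_j: "Angle2D | float",
    det_j: DetectorGeometry,
) -> Direction3D:
    """Intersect two views' solution planes into one 3D direction.

    The intersection line is the cross product of the two plane normals;
    its sign is fixed so the direction's projection onto the first
    detector points along ``theta_i`` (the 2D angle is a full-circle
    direction, so this information exists).
    """
    ns_i = solution_plane_normal(theta_i, det_i)
    ns_j = solution_plane_normal(theta_j, det_j)
    d = np.cross(ns_i, ns_j)
    norm = np.linalg.norm(d)
    if norm < 1e-9:
        raise DegenerateTriangulationError(
            "solution planes are parallel (identical or opposite views)"
        )
    d = d / norm
    v_i = angle_to_world_vector(theta_i, det_i)
    d_in_plane = d - (d @ det_i.normal) * det_i.normal
    if float(d_in_plane @ v_i) < 0.0:
        d = -d
    return Direction3D(d)


def angular_distance(d1: Direction3D, d2: Direction3D) -> float:
    """Great-circle distance (radians) between two directions.

    Uses the spherical law of cosines on elevation/azimuth, which with
    this package's angle convention equals ``arccos(d1.vec @ d2.vec)``.
    The arccos argument is clamped against rounding.
    """
    c = (
        math.sin(d1.theta) * math.sin(d2.theta)
        + math.cos(d1.theta) * math.cos(d2.theta) * math.cos(d1.phi - d2.phi)
    )
    return math.acos(min(1.0, max(-1.0, c)))


def mean_direction(directions: "list[Direction3D] | tuple[Direction3D, ...]") -> Direction3D:
    """Hemisphere-aligned normalized mean of a set of directions.

    Estimates after the first are flipped if they point into the opposite
    hemisphere, then the arithmetic mean of the unit vectors is
    renormalized. Raises :class:`UndefinedMeanError` if the mean vanishes.
    """
    ref = directions[0].vec
    acc = np.zeros(3)
    for d in directions:
        v = d.vec if float(d.vec @ ref) >= 0.0 else -d.vec
        acc += v
    acc /= len(directions)
    if np.linalg.norm(acc) < 1e-9:
        raise UndefinedMeanError("aligned mean direction is undefined (zero vector)")
    return Direction3D(acc)


def aggregate_estimates(
    pairwise: "list[Direction3D] | tuple[Direction3D, ...]",
    tau: float = DEFAULT_TAU,
) -> EstimateSet:
    """Apply the agreement filter to the three pairwise 3D estimates.

    Computes the mean pairwise great-circle distance d-bar; the set is
    accepted iff d-bar < tau, in which case the hemisphere-aligned mean of
    the three estimates is the output direction.
    """
    if len(pairwise) != 3:
        raise GeometryError(f"expected exactly 3 pairwise estimates, got {len(pairwise)}")
    d12 = angular_distance(pairwise[0], pairwise[1])
    d13 = angular_distance(pairwise[0], pairwise[2])
    d23 = angular_distance(pairwise[1], pairwise[2])
    d_bar = (d12 + d13 + d23) / 3.0
    accepted = d_bar < tau
    mean: Direction3D | None = None
    diagnostic = None
    if accepted:
        try:
            mean = mean_direction(pairwise)
        except UndefinedMeanError:
            accepted = False
            mean = None
            diagnostic = "undefined mean direction"
    return EstimateSet(
        pairwise=tuple(pairwise),
        mean_distance=d_bar,
        accepted=accepted,
        mean_direction=mean,
        diagnostic=diagnostic,
    )
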