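"""Synthetic bulb phantoms and parallel-beam x-ray projection.

No imaging data accompanies the growth-direction task, so this module
generates voxel phantoms that emulate a tulip-type bulb: a prolate
ellipsoidal body wrapped in concentric high-contrast shells (the scales),
a central shaft running from the basal root plate to the tip, a dense
basal disc, and a protruding tip cone. Optional confounders reproduce the
known hard cases: a bent shaft, low shell contrast, and an attached
lateral bulblet. The ground-truth growth vector (basal plate to tip) is
the +z axis of the volume frame.

Radiograph triplets are simulated by a parallel-beam line-integral
projector: each detector pixel integrates attenuation along the ray
anti-parallel to the detector normal, with trilinear sampling at a step
of half a voxel. Parallel geometry matches the direction-only 2D-to-3D
mapping, which uses no source position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .features import Radiograph
from .geometry import (
    DetectorGeometry,
    Direction3D,
    build_detector_ring,
    project_direction,
)

__all__ = [
    "PhantomError",
    "TruncationError",
    "Morphology",
    "BulbPhantom",
    "Pose",
    "ProjectionTriplet",
    "BulbDataset",
    "generate_phantom",
    "random_pose",
    "forward_project",
    "project_triplet",
    "make_dataset",
    "DEFAULT_MORPHOLOGY",
]


class PhantomError(ValueError):
    """Base class for phantom-construction failures."""


class TruncationError(PhantomError):
    """The posed phantom does not fit in the detector field of view."""


@dataclass(frozen=True)
class Morphology:
    """Geometric and attenuation parameters of one synthetic bulb.

    Lengths in mm, attenuation in 1/mm. The defaults describe a ~50 mm
    tulip-type bulb: body semi-axes (transverse, axial), five shells with
    strong contrast, a straight 3 mm-radius shaft, an 8 mm protruding tip
    and a dense 3 mm basal plate.
    """

    body_radius_xy: float = 15.0
    body_radius_z: float = 22.0
    n_shells: int = 5
    shell_contrast: float = 0.8
    shaft_radius: float = 3.0
    shaft_bend: float = 0.0  # lateral tip offset (mm) of a quadratic bend
    tip_length: float = 8.0
    tip_radius: float = 4.0
    root_plate_thickness: float = 3.0
    root_plate_radius: float = 8.0
    bulblet_radius: float = 0.0  # 0 disables the attached bulblet
    base_attenuation: float = 0.02
    shaft_attenuation_factor: float = 2.0
    root_attenuation_factor: float = 2.5
    tip_attenuation_factor: float = 1.2
    noise_amplitude: float = 0.05

    def bounding_radius(self) -> float:
        """Radius (mm) of a sphere containing the whole bulb."""
        r = max(self.body_radius_xy, self.body_radius_z + self.tip_length)
        if self.bulblet_radius > 0.0:
            r = max(r, self.body_radius_xy + 2.0 * self.bulblet_radius)
        return r


DEFAULT_MORPHOLOGY = Morphology()


@dataclass(frozen=True)
class BulbPhantom:
    """Voxel attenuation volume with its ground-truth growth vector.

    ``volume`` is an isotropic 3D array of linear attenuation (1/mm)
    indexed (x, y, z), centred on the volume frame origin; ``growth_vec``
    points from the basal plate to the tip in the volume frame.
    """

    volume: np.ndarray
    voxel_size: float
    growth_vec: np.ndarray
    morphology: Morphology
    seed: int | None = None
    phantom_id: str = "phantom"
    #: overrides the morphology-derived content radius (mm) for volumes
    #: built by hand rather than by generate_phantom
    bounding_radius_mm: float | None = None

    def content_radius(self) -> float:
        """Radius (mm) of the centred sphere containing all attenuation."""
        if self.bounding_radius_mm is not None:
            return self.bounding_radius_mm
        return self.morphology.bounding_radius()


@dataclass(frozen=True)
class Pose:
    """A rigid orientation of the bulb on the belt (world <- volume)."""

    rotation: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        if r.shape != (3, 3):
            raise PhantomError("pose rotation must be a 3x3 matrix")
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-9) or np.linalg.det(r) < 0.0:
            raise PhantomError("pose rotation must be a proper rotation matrix")
        object.__setattr__(self, "rotation", r)


@dataclass(frozen=True)
class ProjectionTriplet:
    """Three simultaneous radiographs of one posed bulb with ground truth."""

    radiographs: tuple[Radiograph, Radiograph, Radiograph]
    detectors: tuple[DetectorGeometry, DetectorGeometry, DetectorGeometry]
    true_direction: Direction3D
    true_angles: tuple[float, float, float]
    phantom_id: str
    pose_id: int


@dataclass(frozen=True)
class BulbDataset:
    """Phantoms plus the projection triplets simulated from them."""

    phantoms: tuple[BulbPhantom, ...]
    triplets: tuple[ProjectionTriplet, ...]
    detectors: tuple[DetectorGeometry, DetectorGeometry, DetectorGeometry]


def generate_phantom(
    morphology: Morphology = DEFAULT_MORPHOLOGY,
    seed: int | None = None,
    size: int = 128,
    voxel_size: float = 0.5,
    phantom_id: str = "phantom",
) -> BulbPhantom:
    """Build a voxel bulb phantom; deterministic given the seed.

    The growth axis is +z in the volume frame. Raises
    :class:`PhantomError` when the morphology does not fit inside the
    volume with a one-voxel margin.
    """
    m = morphology
    half_extent = size * voxel_size / 2.0
    if m.bounding_radius() >= half_extent - voxel_size:
        raise PhantomError("bulb morphology exceeds the phantom volume")
    ax = np.arange(size, dtype=np.float64)
    coords = (ax - (size - 1) / 2.0) * voxel_size
    x, y, z = np.meshgrid(coords, coords, coords, indexing="ij")

    mu = np.zeros((size, size, size), dtype=np.float64)
    # ellipsoidal body with sinusoidal concentric shells
    rho2 = (x**2 + y**2) / m.body_radius_xy**2 + z**2 / m.body_radius_z**2
    body = rho2 <= 1.0
    rho = np.sqrt(rho2, where=body, out=np.zeros_like(rho2))
    shells = 1.0 + 0.5 * m.shell_contrast * np.cos(2.0 * math.pi * m.n_shells * rho)
    mu[body] = m.base_attenuation * shells[body]

    z_base = -m.body_radius_z
    z_top = m.body_radius_z
    # central shaft, optionally bent: lateral offset grows quadratically
    # from the basal plate so the offset at the tip equals shaft_bend
    frac_up = (z - z_base) / (z_top - z_base)
    offset = m.shaft_bend * np.clip(frac_up, 0.0, 1.0) ** 2
    shaft = ((x - offset) ** 2 + y**2 <= m.shaft_radius**2) & (z >= z_base) & (z <= z_top)
    mu[shaft & body] = m.base_attenuation * m.shaft_attenuation_factor

    # basal root plate: dense disc at the bottom pole
    plate = (
        (x**2 + y**2 <= m.root_plate_radius**2)
        & (z >= z_base)
        & (z <= z_base + m.root_plate_thickness)
    )
    mu[plate] = m.base_attenuation * m.root_attenuation_factor

    # protruding tip cone from just below the top pole
    tip_z0 = z_top - 0.05 * m.body_radius_z
    tip_frac = (z - tip_z0) / (z_top + m.tip_length - tip_z0)
    in_tip = (tip_frac >= 0.0) & (tip_frac <= 1.0)
    tip_r = m.tip_radius * (1.0 - np.clip(tip_frac, 0.0, 1.0))
    tip = in_tip & ((x - m.shaft_bend) ** 2 + y**2 <= tip_r**2)
    mu[tip] = m.base_attenuation * m.tip_attenuation_factor

    # optional lateral bulblet
    if m.bulblet_radius > 0.0:
        bx = m.body_radius_xy + 0.6 * m.bulblet_radius
        bz = -0.3 * m.body_radius_z
        bulblet = (
            (x - bx) ** 2 / m.bulblet_radius**2
            + y**2 / (0.8 * m.bulblet_radius) ** 2
            + (z - bz) ** 2 / (1.3 * m.bulblet_radius) ** 2
        ) <= 1.0
        mu[bulblet] = np.maximum(mu[bulblet], m.base_attenuation * 1.1)

    if m.noise_amplitude > 0.0 and seed is not None:
        rng = np.random.default_rng(seed)
        noise = ndimage.gaussian_filter(rng.standard_normal(mu.shape), 1.5)
        noise /= max(noise.std(), 1e-12)
        mu *= np.clip(1.0 + m.noise_amplitude * noise, 0.0, None)

    return BulbPhantom(
        volume=mu.astype(np.float32),
        voxel_size=voxel_size,
        growth_vec=np.array([0.0, 0.0, 1.0]),
        morphology=m,
        seed=seed,
        phantom_id=phantom_id,
    )


def random_pose(seed_or_rng: "int | np.random.Generator") -> Pose:
    """Draw a rotation uniformly from SO(3); deterministic given a seed."""
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    return Pose(rotation=Rotation.random(rng=rng).as_matrix())


def forward_project(
    phantom: BulbPhantom,
    pose: Pose,
    det: DetectorGeometry,
    n_pixels: int = 160,
    pixel_size: float = 0.6,
    step_fraction: float = 0.5,
) -> Radiograph:
    """Parallel-beam line-integral radiograph of a posed phantom.

    Rays run anti-parallel to the detector normal through each pixel
    centre; attenuation is sampled by trilinear interpolation at a step
    of ``step_fraction`` voxels along the segment where the ray crosses
    the volume box. The pixel grid is centred on the detector origin.
    """
    half_fov = n_pixels * pixel_size / 2.0
    if phantom.content_radius() > half_fov:
        raise TruncationError("posed bulb exceeds the detector field of view")

    size = phantom.volume.shape[0]
    vox = phantom.voxel_size
    half = size * vox / 2.0
    rot_inv = pose.rotation.T  # volume <- world

    # pixel centres in world coordinates, expressed in the volume frame
    u = (np.arange(n_pixels) - (n_pixels - 1) / 2.0) * pixel_size
    uu, vv = np.meshgrid(u, u, indexing="xy")  # vv: rows (axis_y), uu: cols
    p0_world = (
        uu[..., None] * det.axis_x + vv[..., None] * det.axis_y + det.origin
    )  # (H, W, 3)
    p0 = (p0_world @ rot_inv.T).reshape(-1, 3)
    d = rot_inv @ det.normal  # ray direction in the volume frame (unit)

    # the bulb lies inside a centred sphere (attenuation is zero outside),
    # so clip each ray to that sphere and skip rays that miss it entirely
    radius = min(phantom.content_radius() + 2.0 * vox, half * math.sqrt(3.0))
    pd = p0 @ d
    disc = pd**2 - (np.sum(p0**2, axis=1) - radius**2)
    hit = disc > 0.0
    integral = np.zeros(p0.shape[0])
    if hit.any():
        sq = np.sqrt(disc[hit])
        t0 = -pd[hit] - sq
        t1 = -pd[hit] + sq
        span = t1 - t0
        step = step_fraction * vox
        n_steps = max(int(math.ceil(span.max() / step)), 1)
        dt = span / n_steps  # per-ray step, <= step by construction
        offs = (np.arange(n_steps) + 0.5)[None, :]
        ts = t0[:, None] + offs * dt[:, None]  # (n_hit, n_steps)
        coords = np.empty((3, ts.shape[0], n_steps), dtype=np.float64)
        p0h = p0[hit]
        for axis in range(3):
            np.multiply(ts, d[axis], out=coords[axis])
            coords[axis] += p0h[:, axis, None]
            coords[axis] /= vox
            coords[axis] += (size - 1) / 2.0
        vals = ndimage.map_coordinates(
            phantom.volume,
            coords.reshape(3, -1),
            order=1,
            mode="constant",
            cval=0.0,
            prefilter=False,
        ).reshape(ts.shape)
        integral[hit] = vals.sum(axis=1) * dt
    integral = integral.reshape(uu.shape)
    return Radiograph(np.maximum(integral, 0.0), pixel_size=pixel_size)


def project_triplet(
    phantom: BulbPhantom,
    pose: Pose,
    detectors: "tuple[DetectorGeometry, ...] | list[DetectorGeometry]",
    pose_id: int = 0,
    n_pixels: int = 160,
    pixel_size: float = 0.6,
    step_fraction: float = 0.5,
) -> ProjectionTriplet:
    """Simulate the three-view radiograph triplet of one posed bulb."""
    true_dir = Direction3D(pose.rotation @ phantom.growth_vec)
    radiographs = tuple(
        forward_project(
            phantom, pose, det, n_pixels=n_pixels, pixel_size=pixel_size,
            step_fraction=step_fraction,
        )
        for det in detectors
    )
    true_angles = tuple(float(project_direction(true_dir, det)) for det in detectors)
    return ProjectionTriplet(
        radiographs=radiographs,  # type: ignore[arg-type]
        detectors=tuple(detectors),  # type: ignore[arg-type]
        true_direction=true_dir,
        true_angles=true_angles,  # type: ignore[arg-type]
        phantom_id=phantom.phantom_id,
        pose_id=pose_id,
    )


def _jitter_morphology(rng: np.random.Generator, base: Morphology) -> Morphology:
    """Draw one bulb's morphology from realistic per-bulb ranges.

    Shell count 3-7, shell contrast 0.4-1.2 (the low end emulating the
    low-contrast confounder), mild size variation, a bent shaft in about
    a third of bulbs and an attached bulblet in about a fifth.
    """
    bend = float(rng.uniform(2.0, 6.0)) if rng.random() < 0.35 else 0.0
    bulblet = float(rng.uniform(4.0, 6.5)) if rng.random() < 0.2 else 0.0
    return replace(
        base,
        body_radius_xy=float(rng.uniform(13.0, 17.0)),
        body_radius_z=float(rng.uniform(19.0, 24.0)),
        n_shells=int(rng.integers(3, 8)),
        shell_contrast=float(rng.uniform(0.4, 1.2)),
        shaft_radius=float(rng.uniform(2.5, 3.5)),
        shaft_bend=bend,
        tip_length=float(rng.uniform(5.0, 7.0)),
        tip_radius=float(rng.uniform(3.0, 5.0)),
        bulblet_radius=bulblet,
    )


def make_dataset(
    n_phantoms: int,
    poses_per_phantom: int,
    ring: "tuple[DetectorGeometry, ...] | list[DetectorGeometry] | None" = None,
    seed: int = 0,
    base_morphology: Morphology = DEFAULT_MORPHOLOGY,
    size: int = 128,
    voxel_size: float = 0.5,
    n_pixels: int = 160,
    pixel_size: float = 0.6,
) -> BulbDataset:
    """Simulate a reproducible multi-bulb, multi-pose projection dataset.

    Each phantom's morphology is jittered from per-bulb ranges; each pose
    is an independent uniform rotation; each posed bulb yields one
    three-view triplet from the 60-degree ring with its ground-truth 3D
    direction and per-view 2D labels.
    """
    if n_phantoms < 2:
        raise PhantomError("need at least 2 phantoms for leave-one-bulb-out")
    if ring is None:
        ring = build_detector_ring()
    rng = np.random.default_rng(seed)
    phantoms = []
    triplets = []
    for p in range(n_phantoms):
        morph = _jitter_morphology(rng, base_morphology)
        ph_seed = int(rng.integers(2**31))
        phantom = generate_phantom(
            morph, seed=ph_seed, size=size, voxel_size=voxel_size,
            phantom_id=f"bulb_{p:03d}",
        )
        phantoms.append(phantom)
        for q in range(poses_per_phantom):
            pose = random_pose(int(rng.integers(2**31)))
            triplets.append(
                project_triplet(
                    phantom, pose, ring, pose_id=q,
                    n_pixels=n_pixels, pixel_size=pixel_size,
                )
            )
    return BulbDataset(
        phantoms=tuple(phantoms), triplets=tuple(triplets), detectors=tuple(ring)
    )
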