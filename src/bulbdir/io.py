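"""Plain-text / TIFF interchange for detector rings, features and results."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .features import FEATURE_NAMES
from .geometry import (
    DetectorGeometry,
    aggregate_estimates,
    triangulate_pair,
    DEFAULT_TAU,
)
from .phantom import BulbPhantom, ProjectionTriplet

__all__ = [
    "load_radiograph",
    "save_detector_ring",
    "load_detector_ring",
    "features_to_csv",
    "save_triplets",
    "export_phantom",
    "batch_triangulate_csv",
]


def load_radiograph(path: str, pixel_size: float = 1.0) -> "Radiograph":
    """Read a single-channel TIFF/PNG (integer or float) as a Radiograph."""
    from .features import Radiograph

    p = str(path)
    if p.lower().endswith((".tif", ".tiff")):
        arr = tifffile.imread(p)
    else:
        from PIL import Image

        arr = np.asarray(Image.open(p))
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 3:  # collapse an accidental channel axis
        arr = arr.mean(axis=-1)
    return Radiograph(arr, pixel_size=pixel_size)


def save_detector_ring(detectors, path: str) -> None:
    """Write per-detector origin and in-plane axes (mm) as YAML."""
    payload = [
        {
            "origin": [float(v) for v in det.origin],
            "axis_x": [float(v) for v in det.axis_x],
            "axis_y": [float(v) for v in det.axis_y],
        }
        for det in detectors
    ]
    with open(path, "w") as fh:
        yaml.safe_dump({"detectors": payload}, fh, sort_keys=False)


def load_detector_ring(path: str) -> list[DetectorGeometry]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return [
        DetectorGeometry(
            origin=np.array(d["origin"], dtype=float),
            axis_x=np.array(d["axis_x"], dtype=float),
            axis_y=np.array(d["axis_y"], dtype=float),
        )
        for d in payload["detectors"]
    ]


def features_to_csv(feature_rows, path: str, index=None) -> None:
    """One row per image, 105 columns with stable headers."""
    df = pd.DataFrame(np.atleast_2d(np.asarray(feature_rows)), columns=list(FEATURE_NAMES))
    if index is not None:
        df.insert(0, "image_id", index)
    df.to_csv(path, index=False)


def save_triplets(triplets, out_dir: str) -> pd.DataFrame:
    """Export radiographs as TIFF plus a ground-truth manifest CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for t in triplets:
        for view, (rad, det, theta) in enumerate(
            zip(t.radiographs, t.detectors, t.true_angles)
        ):
            name = f"{t.phantom_id}_pose{t.pose_id:04d}_view{view}.tif"
            tifffile.imwrite(out / name, rad.pixels.astype(np.float32))
            rows.append(
                {
                    "phantom_id": t.phantom_id,
                    "pose_id": t.pose_id,
                    "view": view,
                    "file": name,
                    "pixel_size_mm": rad.pixel_size,
                    "det_origin": json.dumps([float(v) for v in det.origin]),
                    "det_axis_x": json.dumps([float(v) for v in det.axis_x]),
                    "det_axis_y": json.dumps([float(v) for v in det.axis_y]),
                    "theta_2d_true": theta,
                    "theta_3d_true": t.true_direction.theta,
                    "phi_3d_true": t.true_direction.phi,
                }
            )
    manifest = pd.DataFrame.from_records(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def export_phantom(phantom: BulbPhantom, path_prefix: str) -> None:
    """Raw float volume plus a JSON sidecar (dims, voxel size, truth)."""
    vol = phantom.volume.astype(np.float32)
    vol.tofile(path_prefix + ".raw")
    sidecar = {
        "shape": list(vol.shape),
        "dtype": "float32",
        "voxel_size_mm": phantom.voxel_size,
        "growth_vec": [float(v) for v in phantom.growth_vec],
        "phantom_id": phantom.phantom_id,
        "seed": phantom.seed,
    }
    with open(path_prefix + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def batch_triangulate_csv(
    angles_csv: str, ring, out_csv: str, tau: float = DEFAULT_TAU
) -> pd.DataFrame:
    """Triangulate batches of per-view 2D angles from CSV.

    Input columns: ``case_id`` (grouping key), ``view_id`` (0..2),
    ``theta_radians``. Output: one row per case with the filtered mean
    direction (theta, phi, vec components), d-bar and acceptance.
    """
    df = pd.read_csv(angles_csv)
    rows = []
    for case_id, grp in df.groupby("case_id"):
        grp = grp.sort_values("view_id")
        thetas = grp["theta_radians"].to_numpy()
        pairwise = [
            triangulate_pair(thetas[0], ring[0], thetas[1], ring[1]),
            triangulate_pair(thetas[0], ring[0], thetas[2], ring[2]),
            triangulate_pair(thetas[1], ring[1], thetas[2], ring[2]),
        ]
        est = aggregate_estimates(pairwise, tau)
        mean = est.mean_direction
        rows.append(
            {
                "case_id": case_id,
                "theta": mean.theta if mean else np.nan,
                "phi": mean.phi if mean else np.nan,
                "vec_x": mean.vec[0] if mean else np.nan,
                "vec_y": mean.vec[1] if mean else np.nan,
                "vec_z": mean.vec[2] if mean else np.nan,
                "d_bar": est.mean_distance,
                "accepted": est.accepted,
            }
        )
    out = pd.DataFrame.from_records(rows)
    out.to_csv(out_csv, index=False)
    return out
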