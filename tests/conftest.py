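"""Shared fixtures.

The benchmark dataset (20 bulbs x 50 poses at the evaluation resolution)
and the leave-one-bulb-out reports built from it are session-scoped:
they are expensive and shared by the acceptance-style end-to-end tests.
Unit tests use small, fast phantoms.
"""

from __future__ import annotations

import numpy as np
import pytest

from bulbdir.geometry import build_detector_ring
from bulbdir.phantom import generate_phantom, make_dataset, random_pose, project_triplet
from bulbdir.pipeline import (
    evaluate_leave_one_out,
    leave_one_out_2d_errors,
    triplet_features,
)

# evaluation-resolution profile: 96^3 voxels at 0.667 mm, 128x128 detector
# at 0.7 mm (the library default is finer; see docs/methods.md)
EVAL_PROFILE = dict(size=96, voxel_size=0.667, n_pixels=128, pixel_size=0.7)


@pytest.fixture(scope="session")
def ring():
    return build_detector_ring()


@pytest.fixture(scope="session")
def bench_dataset(ring):
    """20 bulbs x 50 poses: the leave-one-bulb-out benchmark."""
    return make_dataset(20, 50, ring=ring, seed=7, **EVAL_PROFILE)


@pytest.fixture(scope="session")
def bench_features(bench_dataset):
    return {id(t): triplet_features(t) for t in bench_dataset.triplets}


@pytest.fixture(scope="session")
def ann_report(bench_dataset, bench_features):
    return evaluate_leave_one_out(
        bench_dataset, "ann", seed=3, features_cache=bench_features
    )


@pytest.fixture(scope="session")
def svr_errors_2d(bench_dataset, bench_features):
    return leave_one_out_2d_errors(
        bench_dataset, "svr", seed=3, features_cache=bench_features
    )


@pytest.fixture(scope="session")
def small_phantom():
    """A coarse default bulb for unit tests (64^3 at 1 mm)."""
    return generate_phantom(seed=11, size=64, voxel_size=1.0)


@pytest.fixture(scope="session")
def small_triplet(small_phantom, ring):
    pose = random_pose(21)
    return project_triplet(
        small_phantom, pose, ring, n_pixels=96, pixel_size=0.9
    )
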