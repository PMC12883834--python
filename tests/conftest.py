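"""Shared fixtures: small synthetic datasets and toy volumes."""

from __future__ import annotations

import numpy as np
import pytest

from evoselect.datatypes import SiteTable, VolumeMap
from evoselect.fixtures import FixtureConfig, make_dataset


def make_volume(grid, voxel_size=2.0, origin=None, network_id="net"):
    """3D volume with a diagonal affine; origin defaults to centering."""
    grid = np.asarray(grid, dtype=float)
    affine = np.diag([voxel_size] * 3 + [1.0])
    if origin is None:
        origin = -(np.array(grid.shape) - 1) / 2.0 * voxel_size
    affine[:3, 3] = origin
    return VolumeMap(grid=grid, affine=affine, network_id=network_id)


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced planted dataset reused by read-only tests."""
    config = FixtureConfig(
        n_genes=200,
        n_sites=80,
        n_networks=8,
        n_branches=4,
        n_clusters=20,
        n_domains=2,
        grid_shape=(12, 12, 12),
        seed=11,
    )
    return make_dataset(config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_sites():
    coords = np.array(
        [
            [0.0, 0.0, 0.0],
            [1.0, 0.0, 0.0],  # dense pair, nn distance 1 mm
            [10.0, 10.0, 10.0],  # sparse
            [-8.0, 6.0, -4.0],  # sparse
        ]
    )
    return SiteTable(site_ids=["a", "b", "c", "d"], coords=coords)
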