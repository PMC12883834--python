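"""Projection of volumetric network z-maps onto biopsy sites.

Each biopsy site receives one value per network, F(n, s), by a
density-adaptive rule: where sites are tightly packed (squared distance
to the nearest other site at or below a threshold, default 5 mm^2) the
z-score of the nearest voxel is taken directly, so closely spaced sites
do not blur into each other; where sites are sparse, a Gaussian-weighted
average of surrounding voxel z-scores is used (mu = 0 mm, sigma = 20 mm
on the site-to-voxel-center distance), filling sparsely sampled regions
with a smooth, representative network signal.

The Gaussian average runs over all finite voxels within a support
radius (default 3 sigma, beyond which weights are negligible) and is
normalized by the weight sum, so a constant volume projects to that
constant under either rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .datatypes import FNSiteMatrix, SiteTable, VolumeMap

logger = logging.getLogger(__name__)


@dataclass
class ProjectionParams:
    """Parameters of the density-adaptive projection rule.

    density_threshold
        Squared Euclidean distance (mm^2) to the nearest other site at
        or below which the direct nearest-voxel rule applies.
    gauss_mu, gauss_sigma
        Mean and width (mm) of the Gaussian distance weighting used in
        the sparse regime.
    support_radius
        Neighborhood radius (mm) of the Gaussian average; ``None``
        means 3 * sigma.
    """

    density_threshold: float = 5.0
    gauss_mu: float = 0.0
    gauss_sigma: float = 20.0
    support_radius: float | None = None

    def __post_init__(self) -> None:
        if self.density_threshold <= 0:
            raise ValueError("density_threshold must be > 0")
        if self.gauss_sigma <= 0:
            raise ValueError("gauss_sigma must be > 0")

    @property
    def radius(self) -> float:
        return 3.0 * self.gauss_sigma if self.support_radius is None else self.support_radius


def nn_sq_distance(sites: SiteTable) -> np.ndarray:
    """Squared Euclidean distance (mm^2) from each site to its nearest other site."""
    if len(sites) < 2:
        raise ValueError("nearest-neighbor distance needs at least 2 sites")
    tree = cKDTree(sites.coords)
    _, idx = tree.query(sites.coords, k=2)
    # square the coordinate differences directly so an exactly
    # representable squared distance (e.g. 1^2 + 2^2 = 5) stays exact
    # at the inclusive density-threshold boundary
    diff = sites.coords - sites.coords[idx[:, 1]]
    return (diff**2).sum(axis=1)


def _nearest_voxel(volume: VolumeMap, site_mm: np.ndarray) -> tuple[tuple[int, ...], float]:
    """Index of the in-grid voxel whose center is nearest the site.

    Ties are broken toward the lexicographically smallest voxel index.
    """
    inv = np.linalg.inv(volume.affine)
    vox = inv[:3, :3] @ site_mm + inv[:3, 3]
    base = np.floor(vox).astype(int)
    best = None
    shape = volume.grid.shape
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                idx = base + (dx, dy, dz)
                idx = np.clip(idx, 0, np.array(shape) - 1)
                center = volume.affine[:3, :3] @ idx + volume.affine[:3, 3]
                d = float(np.linalg.norm(center - site_mm))
                key = (d, tuple(int(i) for i in idx))
                if best is None or key < best:
                    best = key
    assert best is not None
    return best[1], best[0]


class _GaussianSupport:
    """Precomputed per-site voxel neighborhoods and Gaussian weights.

    Geometry depends only on the grid, affine and sites, so one support
    object is shared across all volumes of a run.
    """

    def __init__(self, template: VolumeMap, sites: SiteTable, params: ProjectionParams):
        self.centers = template.voxel_centers_mm()
        tree = cKDTree(self.centers)
        self.neighbors: list[np.ndarray] = []
        self.weights: list[np.ndarray] = []
        mu, sigma = params.gauss_mu, params.gauss_sigma
        for site in sites.coords:
            idx = np.asarray(tree.query_ball_point(site, params.radius), dtype=int)
            if idx.size == 0:
                self.neighbors.append(idx)
                self.weights.append(np.empty(0))
                continue
            d = np.linalg.norm(self.centers[idx] - site, axis=1)
            w = np.exp(-((d - mu) ** 2) / (2.0 * sigma**2))
            self.neighbors.append(idx)
            self.weights.append(w)


def _gaussian_value(flat_grid: np.ndarray, idx: np.ndarray, w: np.ndarray) -> float:
    if idx.size == 0:
        return np.nan
    z = flat_grid[idx]
    finite = np.isfinite(z)
    if not finite.any():
        return np.nan
    wf = w[finite]
    return float(np.dot(wf, z[finite]) / wf.sum())


def project_network(
    volume: VolumeMap,
    sites: SiteTable,
    params: ProjectionParams | None = None,
    *,
    nn_sq: np.ndarray | None = None,
    support: _GaussianSupport | None = None,
) -> np.ndarray:
    """Project one network volume onto all sites; returns a length-n_sites vector.

    The dense rule (nearest-voxel z) applies to sites whose squared
    nearest-neighbor distance is at or below ``density_threshold``; all
    other sites get the Gaussian-weighted voxel average.  Sites with no
    finite voxel in support come back NaN.
    """
    params = params or ProjectionParams()
    if nn_sq is None:
        nn_sq = nn_sq_distance(sites)
    if support is None:
        support = _GaussianSupport(volume, sites, params)
    flat = volume.grid.reshape(-1)
    out = np.full(len(sites), np.nan)
    n_missing = 0
    for i, site in enumerate(sites.coords):
        if nn_sq[i] <= params.density_threshold:
            idx, _ = _nearest_voxel(volume, site)
            z = volume.grid[idx]
            if np.isfinite(z):
                out[i] = float(z)
                continue
            # nearest voxel carries no data: fall through to the smooth rule
            logger.debug(
                "site %s: nearest voxel non-finite, using Gaussian rule",
                sites.site_ids[i],
            )
        out[i] = _gaussian_value(flat, support.neighbors[i], support.weights[i])
        if not np.isfinite(out[i]):
            n_missing += 1
    if n_missing:
        logger.warning(
            "network %s: %d sites had no finite voxel in support", volume.network_id, n_missing
        )
    return out


def project_all(
    volumes: list[VolumeMap],
    sites: SiteTable,
    params: ProjectionParams | None = None,
) -> FNSiteMatrix:
    """Project every network volume onto the sites; rows follow volume order."""
    params = params or ProjectionParams()
    if not volumes:
        return FNSiteMatrix([], list(sites.site_ids), np.empty((0, len(sites))))
    ref = volumes[0]
    for v in volumes[1:]:
        if v.grid.shape != ref.grid.shape or not np.allclose(v.affine, ref.affine):
            raise ValueError(
                f"volume {v.network_id!r} grid/affine differs from {ref.network_id!r}"
            )
    nn_sq = nn_sq_distance(sites)
    support = _GaussianSupport(ref, sites, params)
    rows = [
        project_network(v, sites, params, nn_sq=nn_sq, support=support) for v in volumes
    ]
    return FNSiteMatrix(
        [v.network_id for v in volumes], list(sites.site_ids), np.vstack(rows)
    )
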