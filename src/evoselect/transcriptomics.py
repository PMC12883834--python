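"""Gene-expression-to-network correlation, domain clustering, map overlap.

Each gene's spatial expression profile across biopsy sites is compared
with each network's projected site profile by Spearman rank correlation
with pairwise-complete handling of missing cells.  Networks are then
grouped into domains by Ward's minimum-variance hierarchical clustering
of their gene-correlation profiles, with the number of domains chosen
by average silhouette width.  Dice and Pearson coefficients quantify
volumetric overlap between maps.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_score

from .datatypes import (
    CorrelationMatrix,
    DomainAssignment,
    ExpressionMatrix,
    FNSiteMatrix,
    VolumeMap,
)

logger = logging.getLogger(__name__)


def spearman_correlate(G: ExpressionMatrix, F: FNSiteMatrix) -> CorrelationMatrix:
    """Spearman correlation r(g, n) between gene and network site profiles.

    Computed over sites present in both matrices, pair by pair over the
    complete observations of each (gene, network) combination; pairs
    with fewer than 3 complete sites give a missing entry.
    """
    shared = [s for s in G.sites if s in set(F.sites)]
    if not shared:
        raise ValueError("expression and network matrices share no sites")
    gi = [G.sites.index(s) for s in shared]
    fi = [F.sites.index(s) for s in shared]
    expr = G.values[:, gi]
    fn = F.values[:, fi]

    n_genes, n_nets = expr.shape[0], fn.shape[0]
    out = np.full((n_nets, n_genes), np.nan)

    if np.isfinite(expr).all() and np.isfinite(fn).all():
        # no missing cells: rank once, then one matrix product
        re = np.apply_along_axis(stats.rankdata, 1, expr)
        rf = np.apply_along_axis(stats.rankdata, 1, fn)
        re = (re - re.mean(axis=1, keepdims=True)) / _row_norm(re)
        rf = (rf - rf.mean(axis=1, keepdims=True)) / _row_norm(rf)
        out = rf @ re.T
        out = np.clip(out, -1.0, 1.0)
    else:
        for j in range(n_nets):
            fj = fn[j]
            for i in range(n_genes):
                mask = np.isfinite(expr[i]) & np.isfinite(fj)
                if mask.sum() < 3:
                    continue
                rho = stats.spearmanr(expr[i, mask], fj[mask]).statistic
                out[j, i] = rho
    return CorrelationMatrix(list(F.networks), list(G.genes), out)


def _row_norm(x: np.ndarray) -> np.ndarray:
    centered = x - x.mean(axis=1, keepdims=True)
    n = np.sqrt((centered**2).sum(axis=1, keepdims=True))
    n[n == 0] = np.nan
    return n


def cluster_domains(
    r: CorrelationMatrix, k_range: tuple[int, int] = (2, 12)
) -> DomainAssignment:
    """Group networks into domains by Ward clustering of correlation profiles.

    Rows of ``r`` (one correlation profile per network) are clustered
    with Ward's minimum-variance method on squared Euclidean distances;
    for every k in ``k_range`` the tree is cut and the average
    silhouette width computed, and the maximizing k is returned (ties
    broken toward smaller k).  Missing entries are zero-imputed with a
    logged count.
    """
    X = np.array(r.values, dtype=float)
    n_missing = int(np.count_nonzero(~np.isfinite(X)))
    if n_missing:
        logger.warning("zero-imputing %d missing correlation entries", n_missing)
        X[~np.isfinite(X)] = 0.0
    n = X.shape[0]
    kmin, kmax = k_range
    if kmin < 2 or kmax > n - 1 or kmin > kmax:
        raise ValueError(f"k_range {k_range} outside [2, {n - 1}]")

    Z = linkage(X, method="ward")
    D2 = squareform(pdist(X, metric="sqeuclidean"))
    silhouette_by_k: dict[int, float] = {}
    best_k, best_s = None, -np.inf
    for k in range(kmin, kmax + 1):
        labels = fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        s = float(silhouette_score(D2, labels, metric="precomputed"))
        silhouette_by_k[k] = s
        if s > best_s + 1e-12:
            best_k, best_s = k, s
    if best_k is None:
        raise ValueError("no k in range produced a valid partition")
    labels = fcluster(Z, t=best_k, criterion="maxclust")
    # stable domain naming: D1 is the domain of the first network, etc.
    relabel: dict[int, str] = {}
    assignment: dict[str, str] = {}
    for net, lab in zip(r.networks, labels):
        if lab not in relabel:
            relabel[lab] = f"D{len(relabel) + 1}"
        assignment[net] = relabel[lab]
    domains = [relabel[k] for k in relabel]
    return DomainAssignment(
        labels=assignment, domains=domains, k=len(domains), silhouette_by_k=silhouette_by_k
    )


def _check_same_grid(A: VolumeMap, B: VolumeMap) -> None:
    if A.grid.shape != B.grid.shape or not np.allclose(A.affine, B.affine):
        raise ValueError("volumes are not on the same grid")


def dice_overlap(A: VolumeMap, B: VolumeMap, threshold: float = 0.0) -> float:
    """Dice coefficient 2|A∩B| / (|A| + |B|) of thresholded activation masks.

    Masks are ``value > threshold``; 1 means identical nonempty masks,
    0 no overlap.  Two empty masks give 0 with a warning.
    """
    _check_same_grid(A, B)
    with np.errstate(invalid="ignore"):
        a = A.grid > threshold
        b = B.grid > threshold
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        logger.warning("both activation masks empty at threshold %g; Dice set to 0", threshold)
        return 0.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def pearson_overlap(A: VolumeMap, B: VolumeMap) -> float:
    """Voxelwise Pearson correlation over voxels finite in both maps."""
    _check_same_grid(A, B)
    mask = np.isfinite(A.grid) & np.isfinite(B.grid)
    a, b = A.grid[mask], B.grid[mask]
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        logger.warning("constant or empty map in Pearson overlap; returning NaN")
        return float("nan")
    return float(stats.pearsonr(a, b).statistic)


def domain_mean_map(
    volumes: list[VolumeMap], assignment: DomainAssignment, domain: str
) -> VolumeMap:
    """Voxelwise mean z-map over the networks of one domain (NaN-ignoring)."""
    members = set(assignment.members(domain))
    if not members:
        raise ValueError(f"domain {domain!r} has no member networks")
    chosen = [v for v in volumes if v.network_id in members]
    missing = members - {v.network_id for v in chosen}
    if missing:
        raise ValueError(f"no volume provided for networks {sorted(missing)}")
    ref = chosen[0]
    for v in chosen[1:]:
        _check_same_grid(ref, v)
    stack = np.stack([v.grid for v in chosen])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    return VolumeMap(grid=mean, affine=ref.affine.copy(), network_id=f"domain_{domain}")
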