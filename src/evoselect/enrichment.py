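"""Cell-type enrichment of bicluster gene sets.

Bicluster-derived gene sets (one per branch x domain cell) are related
to a cluster-level single-cell mean-expression matrix: expression is
first denoised by zeroing, per cell cluster, every value below the
cluster's 90th percentile; each gene set is then correlated with every
cluster column (point-biserial: product-moment correlation of the
binary set-membership indicator over a shared gene universe against
the filtered expression); correlations are z-scored across clusters
within each branch x domain cell, and clusters exceeding z > 1.96 are
flagged enriched.  Flags are finally collapsed by cluster metadata
(supercluster, class, neurotransmitter), split into neuronal and
non-neuronal cell types, counting presence per metadata group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datatypes import CellTypeMatrix

logger = logging.getLogger(__name__)

CRITICAL_Z = 1.96


@dataclass
class EnrichmentResult:
    """Per (branch, domain) cell: per-cluster correlations, z-scores, flags."""

    clusters: list[str]
    cells: list[tuple[str, str]]  # (branch, domain) in insertion order
    correlations: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    zscores: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    enriched: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    metadata: dict[str, dict] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "clusters": self.clusters,
            "cells": [list(c) for c in self.cells],
            "correlations": {f"{b}|{d}": v.tolist() for (b, d), v in self.correlations.items()},
            "zscores": {f"{b}|{d}": v.tolist() for (b, d), v in self.zscores.items()},
            "enriched": {
                f"{b}|{d}": [bool(x) for x in v] for (b, d), v in self.enriched.items()
            },
        }


def percentile_filter(cells: CellTypeMatrix, pct: float = 90.0) -> CellTypeMatrix:
    """Zero, per cluster column, every value strictly below the pct-th percentile.

    The percentile is the linear-interpolation quantile of the column;
    values equal to the cutoff are kept.  Constant columns are left
    unchanged (every value sits at the percentile).
    """
    if not 0.0 < pct < 100.0:
        raise ValueError("pct must lie in (0, 100)")
    vals = np.array(cells.values, dtype=float)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        finite = np.isfinite(col)
        if not finite.any():
            continue
        cutoff = np.percentile(col[finite], pct)
        col[finite & (col < cutoff)] = 0.0
    return CellTypeMatrix(
        list(cells.genes), list(cells.clusters), vals, metadata=dict(cells.metadata)
    )


def enrich_gene_set(
    genes: set[str],
    cells_filtered: CellTypeMatrix,
    universe: list[str] | None = None,
    statistic: str = "point_biserial",
) -> np.ndarray:
    """Per-cluster association of a gene set with filtered expression.

    ``point_biserial`` (default): Pearson correlation of the binary
    membership indicator over the universe against each cluster's
    expression column.  ``mean_expression``: the mean filtered
    expression of the set's genes per cluster, as an alternative
    statistic.  Clusters whose column is constant give NaN (logged).
    """
    universe = list(universe) if universe is not None else list(cells_filtered.genes)
    gene_set = set(genes)
    unknown = gene_set - set(universe)
    if unknown:
        raise ValueError(f"genes outside the universe: {sorted(unknown)[:5]}")
    indicator = np.array([g in gene_set for g in universe], dtype=float)
    if indicator.sum() == 0 or indicator.sum() == len(universe):
        raise ValueError("gene set must be a proper nonempty subset of the universe")
    row_idx = [cells_filtered.genes.index(g) for g in universe]
    X = cells_filtered.values[row_idx]  # universe x clusters
    if statistic == "mean_expression":
        return X[indicator.astype(bool)].mean(axis=0)
    if statistic != "point_biserial":
        raise ValueError(f"unknown statistic {statistic!r}")
    ind_c = indicator - indicator.mean()
    ind_norm = np.sqrt((ind_c**2).sum())
    Xc = X - X.mean(axis=0, keepdims=True)
    col_norm = np.sqrt((Xc**2).sum(axis=0))
    out = np.full(X.shape[1], np.nan)
    ok = col_norm > 0
    out[ok] = (ind_c @ Xc[:, ok]) / (ind_norm * col_norm[ok])
    if (~ok).any():
        logger.warning("%d constant cluster columns gave undefined correlations", int((~ok).sum()))
    return out


def zscore_binarize(
    correlations: dict[tuple[str, str], np.ndarray],
    clusters: list[str],
    metadata: dict[str, dict],
    critical_z: float = CRITICAL_Z,
) -> EnrichmentResult:
    """Z-score correlations across clusters per (branch, domain); flag z > critical.

    Standardization uses the sample standard deviation over the
    clusters with defined correlations; a cell needs at least 3 defined
    correlations, and zero variance yields no enrichment (logged).
    The enrichment inequality is strict: z exactly at the critical
    value is not flagged.
    """
    result = EnrichmentResult(clusters=list(clusters), cells=list(correlations), metadata=dict(metadata))
    for cell, corr in correlations.items():
        corr = np.asarray(corr, dtype=float)
        if corr.shape != (len(clusters),):
            raise ValueError(f"cell {cell}: expected {len(clusters)} correlations")
        finite = np.isfinite(corr)
        z = np.full(corr.shape, np.nan)
        flags = np.zeros(corr.shape, dtype=bool)
        if finite.sum() < 3:
            logger.warning("cell %s: fewer than 3 defined correlations; skipped", cell)
        else:
            sd = corr[finite].std(ddof=1)
            if sd == 0:
                logger.warning("cell %s: zero variance across clusters; no enrichment", cell)
            else:
                z[finite] = (corr[finite] - corr[finite].mean()) / sd
                flags = np.where(finite, z > critical_z, False)
        result.correlations[cell] = corr
        result.zscores[cell] = z
        result.enriched[cell] = flags
    return result


def collapse(result: EnrichmentResult, by: str) -> dict:
    """Presence counts of enriched clusters per metadata group.

    For each group of ``by`` (supercluster, class or neurotransmitter)
    the count is the number of (branch, domain) cells with at least one
    enriched cluster in that group — presence, not multiplicity.
    Neuronal and non-neuronal clusters are tallied separately.
    """
    if by not in ("supercluster", "class", "neurotransmitter"):
        raise ValueError(f"unknown metadata key {by!r}")
    counts: dict[str, dict[str, int]] = {"neuronal": {}, "non_neuronal": {}}
    for cell in result.cells:
        flags = result.enriched.get(cell)
        if flags is None:
            continue
        seen: set[tuple[str, str]] = set()
        for cluster, flagged in zip(result.clusters, flags):
            if not flagged:
                continue
            meta = result.metadata[cluster]
            group = str(meta[by])
            side = "neuronal" if meta.get("neuronal") else "non_neuronal"
            seen.add((side, group))
        for side, group in seen:
            counts[side][group] = counts[side].get(group, 0) + 1
    return counts
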