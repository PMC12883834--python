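"""Preparation of the selection x correlation analysis matrix.

Four steps turn raw per-branch dN/dS (omega) estimates and the gene x
network correlation matrix into the concatenated matrix the
biclusterer mines:

1. constraint handling — unstable PAML estimates are dropped; in the
   relaxed mode the degenerate outcomes are recoded (dN = 0 and
   identical sequences to omega = 0, dS = 0 to the branch maximum);
2. rank normalization — omega is rank-normalized per branch
   (competition/minimum ranks, denominator counting the strictly
   positive entries of the branch), correlations per gene (maximum
   ranks, denominator the number of networks);
3. gene pools — per branch, high-omega (> 1) and near-zero-omega gene
   pools, harmonized to a common size across branches;
4. concatenation — one branch's normalized omega column next to the
   normalized correlation matrix, restricted to retained genes.

The omega normalization can exceed 1 when a branch contains zeros:
zeros enter the numerator ranking but not the denominator, and the
formula is followed literally (range [0, 1 + eps]).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datatypes import AnalysisMatrix, CorrelationMatrix, OmegaTable

logger = logging.getLogger(__name__)

_LOW_TOL = 1e-9


@dataclass
class NormalizedOmega:
    """Branch-wise rank-normalized omega; same layout as the raw table."""

    genes: list[str]
    branches: list[str]
    values: np.ndarray  # gene x branch, NaN = missing

    def branch_column(self, branch: str) -> np.ndarray:
        return self.values[:, self.branches.index(branch)]


@dataclass
class NormalizedCorrelation:
    """Per-gene rank-normalized correlations with retained-gene flags."""

    genes: list[str]
    networks: list[str]
    values: np.ndarray  # gene x network
    retained: np.ndarray  # bool per gene


@dataclass
class GenePools:
    """Per-branch pre-selected high- and low-omega gene pools."""

    high: dict[str, list[str]] = field(default_factory=dict)
    low: dict[str, list[str]] = field(default_factory=dict)

    def pool(self, branch: str, direction: str) -> list[str]:
        table = {"high": self.high, "low": self.low}[direction]
        return table[branch]


def apply_omega_constraints(raw: OmegaTable, mode: str = "relaxed") -> OmegaTable:
    """Recode or drop omega cells according to their PAML status.

    Stable estimates are kept; unstable and short-edge-unstable cells
    become missing in both modes.  The relaxed mode additionally turns
    dN = 0 cells into 0 (purifying), identical-sequence cells into 0
    (neutral), and dS = 0 cells into the maximum retained omega of the
    branch (adaptive); the conservative mode drops all three.
    """
    if mode not in ("conservative", "relaxed"):
        raise ValueError(f"unknown mode {mode!r}")
    omega = np.array(raw.values, dtype=float)
    status = raw.status
    drop = np.isin(status, ["UNSTABLE", "SHORT_EDGE_UNSTABLE"])
    omega[drop] = np.nan
    degenerate = np.isin(status, ["DN_ZERO", "DS_ZERO", "IDENTICAL"])
    if mode == "conservative":
        omega[degenerate] = np.nan
    else:
        omega[np.asarray(status == "DN_ZERO") | np.asarray(status == "IDENTICAL")] = 0.0
        for j in range(omega.shape[1]):
            ds_zero = np.asarray(status[:, j] == "DS_ZERO")
            if not ds_zero.any():
                continue
            stable = np.asarray(status[:, j] == "STABLE") & np.isfinite(omega[:, j])
            if stable.any():
                omega[ds_zero, j] = omega[stable, j].max()
            else:
                logger.warning(
                    "branch %s: dS=0 cells but no stable omega to take the maximum from",
                    raw.branches[j],
                )
                omega[ds_zero, j] = np.nan
    status_out = np.array(status, dtype=object)
    return OmegaTable(list(raw.genes), list(raw.branches), omega, status=status_out)


def rank_normalize_omega(omega: OmegaTable | NormalizedOmega) -> NormalizedOmega:
    """Per-branch rank normalization with competition (minimum) tie ranks.

    For gene i in branch j:

        omega_norm[i, j] = (1 + #{k != i : omega[k, j] < omega[i, j]})
                           / #{k : omega[k, j] present and > 0}

    so the branch maximum maps to 1 when all entries are positive and
    distinct, and tied values share the smallest rank of the tied
    block.  Missing cells stay missing; a branch with no strictly
    positive entries becomes all-missing (logged).
    """
    values = np.asarray(omega.values, dtype=float)
    out = np.full(values.shape, np.nan)
    branches = list(omega.branches)
    for j, branch in enumerate(branches):
        col = values[:, j]
        present = np.isfinite(col)
        denom = int(np.count_nonzero(present & (col > 0)))
        if denom == 0:
            if present.any():
                logger.warning(
                    "branch %s: no strictly positive omega; column left missing", branch
                )
            continue
        sub = col[present]
        # competition (min) rank = 1 + number of strictly smaller entries
        order = np.argsort(sub, kind="stable")
        ranks = np.empty(sub.size)
        sorted_vals = sub[order]
        min_rank = np.searchsorted(sorted_vals, sorted_vals, side="left") + 1
        ranks[order] = min_rank
        out[present, j] = ranks / denom
    return NormalizedOmega(list(omega.genes), branches, out)


def build_gene_pools(
    omega: OmegaTable,
    high_cut: float = 1.0,
    low_cut: float = 0.0,
    harmonize: bool = True,
    *,
    tol: float = _LOW_TOL,
    rng: np.random.Generator | None = None,
) -> GenePools:
    """Select per-branch high (> high_cut) and low (<= low_cut + tol) omega pools.

    With ``harmonize`` the pools are truncated to the smallest pool
    size across branches: high pools keep their largest-omega genes,
    low pools their smallest.  Passing ``rng`` replaces truncation with
    a seeded random subsample for sensitivity checks.
    """
    genes = np.asarray(omega.genes, dtype=object)
    pools = GenePools()
    for j, branch in enumerate(omega.branches):
        col = omega.values[:, j]
        present = np.isfinite(col)
        hi_mask = present & (col > high_cut)
        lo_mask = present & (col <= low_cut + tol)
        # deterministic extremity ordering; gene label breaks exact ties
        hi_idx = np.flatnonzero(hi_mask)
        hi_idx = hi_idx[np.lexsort((genes[hi_idx], -col[hi_idx]))]
        lo_idx = np.flatnonzero(lo_mask)
        lo_idx = lo_idx[np.lexsort((genes[lo_idx], col[lo_idx]))]
        pools.high[branch] = [str(g) for g in genes[hi_idx]]
        pools.low[branch] = [str(g) for g in genes[lo_idx]]
    if harmonize:
        for table in (pools.high, pools.low):
            target = min(len(v) for v in table.values())
            for branch in table:
                if rng is None:
                    table[branch] = table[branch][:target]
                else:
                    pick = rng.choice(len(table[branch]), size=target, replace=False)
                    table[branch] = [table[branch][i] for i in sorted(pick)]
    for direction, table in (("high", pools.high), ("low", pools.low)):
        for branch, pool in table.items():
            if not pool:
                raise ValueError(
                    f"branch {branch!r}: empty {direction}-omega pool after harmonization"
                )
    return pools


def filter_spatial_genes(
    r: CorrelationMatrix, threshold: float = 0.1, use_absolute: bool = True
) -> set[str]:
    """Genes whose correlation with at least one network exceeds ``threshold``.

    By default the magnitude |r| is compared (a strong negative
    spatial correlation is equally informative); set
    ``use_absolute=False`` for the signed reading.
    """
    vals = np.abs(r.values) if use_absolute else r.values
    with np.errstate(invalid="ignore"):
        keep = np.nanmax(np.where(np.isfinite(vals), vals, -np.inf), axis=0) > threshold
    return {g for g, k in zip(r.genes, keep) if k}


def rank_normalize_correlations(
    r: CorrelationMatrix,
    low_corr_cut: float = 0.1,
    gene_filter_cut: float = 0.75,
    *,
    use_absolute_low_cut: bool = True,
    filter_on_normalized: bool = True,
    zero_minimum: bool = True,
) -> NormalizedCorrelation:
    """Per-gene rank normalization of correlations with maximum tie ranks.

    For gene i and network j:

        r_norm[i, j] = (1 + #{k != j : r[i, k] < r[i, j]}) / n_networks

    with tied values taking the largest rank of the tied block, so each
    gene's best network maps to 1.  Afterwards the per-gene minimum is
    set to 0, rows of genes whose overall correlation with every
    network stays below ``low_corr_cut`` are zeroed entirely, and genes
    are flagged retained when any entry reaches ``gene_filter_cut``
    (on the normalized row by default; ``filter_on_normalized=False``
    applies the cut to raw correlations instead).  Missing raw cells
    are treated as the weakest correlations (normalized to 0).
    """
    n_networks = len(r.networks)
    if n_networks == 0:
        raise ValueError("correlation matrix has no networks")
    raw = r.values.T  # gene x network
    n_genes = raw.shape[0]
    out = np.zeros((n_genes, n_networks))
    for i in range(n_genes):
        row = raw[i]
        present = np.isfinite(row)
        if not present.any():
            continue
        sub = row[present]
        # maximum tie rank = count of entries <= value
        order = np.argsort(sub, kind="stable")
        sorted_vals = sub[order]
        max_rank = np.searchsorted(sorted_vals, sorted_vals, side="right")
        ranks = np.empty(sub.size)
        ranks[order] = max_rank
        out[i, present] = ranks / n_networks
        if zero_minimum:
            # per-gene minimum-zeroing: every entry tied at the row minimum
            row_min = sorted_vals[0]
            out[i, present & (row == row_min)] = 0.0
    mags = np.abs(raw) if use_absolute_low_cut else raw
    with np.errstate(invalid="ignore"):
        max_raw = np.nanmax(np.where(np.isfinite(mags), mags, -np.inf), axis=1)
    low_overall = max_raw < low_corr_cut
    out[low_overall] = 0.0
    if low_overall.any():
        logger.info(
            "zeroed %d genes with all correlations below %g",
            int(low_overall.sum()),
            low_corr_cut,
        )
    if filter_on_normalized:
        retained = (out >= gene_filter_cut).any(axis=1)
    else:
        with np.errstate(invalid="ignore"):
            retained = np.nanmax(
                np.where(np.isfinite(raw), raw, -np.inf), axis=1
            ) > gene_filter_cut
    retained &= ~low_overall
    return NormalizedCorrelation(list(r.genes), list(r.networks), out, retained)


def concatenate(
    omega_norm: NormalizedOmega,
    branch: str,
    r_norm: NormalizedCorrelation,
    genes: set[str] | None = None,
) -> AnalysisMatrix:
    """Build the per-branch [omega_norm(., branch) || r_norm] matrix.

    Rows are restricted to genes present in both inputs (and in
    ``genes`` when given); genes missing the branch's normalized omega
    are dropped with a log entry.
    """
    if branch not in omega_norm.branches:
        raise KeyError(f"branch {branch!r} not in normalized omega table")
    omega_col = omega_norm.branch_column(branch)
    omega_by_gene = dict(zip(omega_norm.genes, omega_col))
    keep: list[str] = []
    dropped = 0
    for g in r_norm.genes:
        if genes is not None and g not in genes:
            continue
        val = omega_by_gene.get(g)
        if val is None or not np.isfinite(val):
            dropped += 1
            continue
        keep.append(g)
    if dropped:
        logger.info("branch %s: dropped %d genes lacking normalized omega", branch, dropped)
    if not keep:
        raise ValueError(f"branch {branch!r}: no genes shared between inputs")
    ridx = [r_norm.genes.index(g) for g in keep]
    block = np.column_stack(
        [np.array([omega_by_gene[g] for g in keep]), r_norm.values[ridx]]
    )
    col_labels = [f"omega:{branch}"] + list(r_norm.networks)
    classes = ["omega"] + ["network"] * len(r_norm.networks)
    return AnalysisMatrix(keep, col_labels, block, column_classes=classes)
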