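"""Genetic-algorithm biclustering of the selection x correlation matrix.

A bicluster B = (g_sub, [b_sub n_sub]) is a gene subset together with a
column subset (one branch's normalized-omega column plus network
columns) such that every gene qualifies in every selected column of a
thresholded incidence matrix.  The search encodes candidates as binary
masks over the network columns (the omega column is forced into every
candidate), evolves several isolated subpopulations with tournament
selection, uniform crossover, per-bit mutation and one elite per
subpopulation, and repeats the search a configurable number of times.
Qualifying cells of emitted biclusters can be masked to zero (a tabu
list) so later searches find different patterns; a global-optimization
wrapper cycles through weighting/tabu parameter combinations; similar
biclusters are merged afterwards and their scores recomputed.

Everything is driven by a single integer seed and fully reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np

from .datatypes import AnalysisMatrix, Bicluster
from .prep import GenePools, NormalizedOmega

logger = logging.getLogger(__name__)


@dataclass
class GabiParams:
    """Search parameters; field names follow the biclusterer's own vocabulary.

    ``popsize`` counts candidate solutions in total, split evenly over
    ``nsubpops`` isolated subpopulations.  ``variableClassNotOnTabuList``
    holds one flag per column class (omega, network): True exempts that
    class from tabu masking, False masks the qualifying cells of every
    emitted bicluster in that class.  ``mutation_rate=None`` means
    1/#columns.  ``do_weighting`` scores omega columns at
    ``weight_omega`` and network columns at ``weight_network`` instead
    of counting both equally.
    """

    amountOfBiclusterSearches: int = 20
    nsubpops: int = 4
    popsize: int = 250
    do_weighting: bool = False
    variableClassNotOnTabuList: tuple[bool, bool] = (True, False)
    global_optim: int = 0
    generations: int = 100
    mutation_rate: float | None = None
    crossover_rate: float = 0.7
    min_genes: int = 5
    min_network_cols: int = 1
    row_consistency: float = 1.0
    weight_omega: float = 2.0
    weight_network: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.popsize < self.nsubpops:
            raise ValueError("popsize must be >= nsubpops")
        for name in ("crossover_rate", "row_consistency"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mutation_rate is not None and not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")
        if self.global_optim < 0:
            raise ValueError("global_optim must be >= 0")


@dataclass
class ThresholdSpec:
    """Per-column qualification thresholds for building the incidence matrix.

    Omega columns qualify inside the closed rank window
    [omega_lo, omega_hi]; network columns qualify at or above
    ``network_min``.  All comparisons are inclusive.
    """

    omega_lo: float = -np.inf
    omega_hi: float = np.inf
    network_min: float = 0.75

    def __post_init__(self) -> None:
        if self.omega_lo > self.omega_hi:
            raise ValueError("omega_lo must be <= omega_hi")


def branch_thresholds(
    omega_norm: NormalizedOmega,
    pools: GenePools,
    branch: str,
    direction: str,
    network_min: float = 0.75,
) -> ThresholdSpec:
    """Branch-specific omega-rank window reproducing the branch's gene pool.

    The cutoff is placed at the pool's extreme normalized rank: a
    high-omega run takes the minimum normalized omega over the
    (harmonized) high pool as lower bound; a low-omega run takes the
    maximum over the low pool as upper bound.  Genes qualifying on the
    omega column are then exactly the pool (up to rank ties).
    """
    if direction not in ("high", "low"):
        raise ValueError(f"direction must be 'high' or 'low', got {direction!r}")
    pool = pools.pool(branch, direction)
    if not pool:
        raise ValueError(f"branch {branch!r}: empty {direction} pool")
    col = omega_norm.branch_column(branch)
    by_gene = dict(zip(omega_norm.genes, col))
    vals = np.array([by_gene[g] for g in pool if g in by_gene], dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError(f"branch {branch!r}: pool has no normalized omega values")
    if direction == "high":
        return ThresholdSpec(omega_lo=float(vals.min()), network_min=network_min)
    return ThresholdSpec(omega_hi=float(vals.max()), network_min=network_min)


def binarize(matrix: AnalysisMatrix, spec: ThresholdSpec) -> np.ndarray:
    """Boolean gene x column incidence of cells meeting their column threshold.

    Missing cells never qualify; comparisons are inclusive.
    """
    inc = np.zeros(matrix.shape, dtype=bool)
    vals = matrix.values
    with np.errstate(invalid="ignore"):
        for j, cls in enumerate(matrix.column_classes):
            col = vals[:, j]
            ok = np.isfinite(col)
            if cls == "omega":
                inc[:, j] = ok & (col >= spec.omega_lo) & (col <= spec.omega_hi)
            else:
                inc[:, j] = ok & (col >= spec.network_min)
    return inc


def score(bicluster: Bicluster, params: GabiParams | None = None) -> float:
    """Bicluster score = size: gene count x (possibly weighted) column count."""
    params = params or GabiParams()
    n_omega = len(bicluster.branches)
    n_net = len(bicluster.networks)
    return _score_counts(len(bicluster.genes), n_omega, n_net, params)


def _score_counts(n_genes: int, n_omega: int, n_net: int, params: GabiParams) -> float:
    if params.do_weighting:
        return float(n_genes * (params.weight_omega * n_omega + params.weight_network * n_net))
    return float(n_genes * (n_omega + n_net))


def _mask_key(mask: np.ndarray) -> tuple[int, ...]:
    return tuple(int(b) for b in mask)


class _Problem:
    """Incidence matrix split into forced omega columns and free network columns."""

    def __init__(
        self,
        incidence: np.ndarray,
        column_classes: list[str],
        gene_labels: list[str],
        column_labels: list[str],
    ):
        incidence = np.asarray(incidence, dtype=bool)
        if incidence.size == 0:
            raise ValueError("incidence matrix is empty")
        if incidence.shape[1] != len(column_classes):
            raise ValueError("one column class required per incidence column")
        self.inc = incidence.copy()
        self.classes = list(column_classes)
        self.genes = list(gene_labels)
        self.columns = list(column_labels)
        self.omega_cols = np.array(
            [i for i, c in enumerate(column_classes) if c == "omega"], dtype=int
        )
        self.net_cols = np.array(
            [i for i, c in enumerate(column_classes) if c == "network"], dtype=int
        )
        if self.net_cols.size == 0:
            raise ValueError("incidence matrix has no network columns")

    @property
    def omega_ok(self) -> np.ndarray:
        if self.omega_cols.size == 0:
            return np.ones(self.inc.shape[0], dtype=bool)
        return self.inc[:, self.omega_cols].all(axis=1)

    def rows_for_mask(self, mask: np.ndarray, row_consistency: float = 1.0) -> np.ndarray:
        sel = self.net_cols[mask]
        if sel.size == 0:
            hits = np.zeros(self.inc.shape[0], dtype=bool)
        elif row_consistency >= 1.0:
            hits = self.inc[:, sel].all(axis=1)
        else:
            need = int(np.ceil(row_consistency * sel.size))
            hits = self.inc[:, sel].sum(axis=1) >= need
        return hits & self.omega_ok


def _evaluate(pop: np.ndarray, problem: _Problem, params: GabiParams) -> np.ndarray:
    """Vectorized fitness of a population of network-column masks."""
    inc_net = problem.inc[:, problem.net_cols].astype(np.float64)
    counts = inc_net @ pop.T.astype(np.float64)  # rows x pop
    sizes = pop.sum(axis=1)
    if params.row_consistency >= 1.0:
        need = sizes.astype(float)
    else:
        need = np.ceil(params.row_consistency * sizes)
    qual = (counts >= need[None, :]) & problem.omega_ok[:, None]
    gene_counts = qual.sum(axis=0)
    n_omega = problem.omega_cols.size
    if params.do_weighting:
        colval = params.weight_omega * n_omega + params.weight_network * sizes
    else:
        colval = n_omega + sizes
    fitness = gene_counts * colval
    invalid = (gene_counts < params.min_genes) | (sizes < params.min_network_cols)
    fitness = np.where(invalid, 0.0, fitness.astype(float))
    return fitness


def _run_ga(
    problem: _Problem, params: GabiParams, rng: np.random.Generator
) -> np.ndarray | None:
    """One GA search; returns the best valid network-column mask or None."""
    n_net = problem.net_cols.size
    n_cols = len(problem.classes)
    mut = params.mutation_rate if params.mutation_rate is not None else 1.0 / n_cols
    subpop_size = max(2, params.popsize // params.nsubpops)
    # sparse initialization: ~2 network columns per candidate keeps early
    # candidates supported by enough genes to create a fitness gradient
    p_init = min(0.5, 2.0 / n_net)

    best_mask: np.ndarray | None = None
    best_fit = 0.0

    for _ in range(params.nsubpops):
        pop = rng.random((subpop_size, n_net)) < p_init
        empty = ~pop.any(axis=1)
        if empty.any():
            pop[empty, rng.integers(0, n_net, size=int(empty.sum()))] = True
        fitness = _evaluate(pop, problem, params)
        for _gen in range(params.generations):
            elite_idx = _argbest(fitness, pop)
            children = np.empty_like(pop)
            children[0] = pop[elite_idx]
            n_children = subpop_size - 1
            a = rng.integers(0, subpop_size, size=(n_children, 2))
            b = rng.integers(0, subpop_size, size=(n_children, 2))
            p1 = np.where(fitness[a[:, 0]] >= fitness[a[:, 1]], a[:, 0], a[:, 1])
            p2 = np.where(fitness[b[:, 0]] >= fitness[b[:, 1]], b[:, 0], b[:, 1])
            cross = rng.random(n_children) < params.crossover_rate
            take_p1 = rng.random((n_children, n_net)) < 0.5
            mixed = np.where(take_p1, pop[p1], pop[p2])
            children[1:] = np.where(cross[:, None], mixed, pop[p1])
            flip = rng.random((subpop_size - 1, n_net)) < mut
            children[1:] ^= flip
            empty = ~children.any(axis=1)
            if empty.any():
                children[empty, rng.integers(0, n_net, size=int(empty.sum()))] = True
            pop = children
            fitness = _evaluate(pop, problem, params)
        idx = _argbest(fitness, pop)
        if fitness[idx] > best_fit or (
            fitness[idx] == best_fit
            and best_mask is not None
            and fitness[idx] > 0
            and _mask_key(pop[idx]) < _mask_key(best_mask)
        ):
            best_fit = float(fitness[idx])
            best_mask = pop[idx].copy()
    if best_fit <= 0 or best_mask is None:
        return None
    return best_mask


def _argbest(fitness: np.ndarray, pop: np.ndarray) -> int:
    """Index of the highest fitness; ties to the lexicographically smallest mask."""
    top = np.flatnonzero(fitness == fitness.max())
    if top.size == 1:
        return int(top[0])
    keys = [_mask_key(pop[i]) for i in top]
    return int(top[min(range(top.size), key=lambda t: keys[t])])


def gabi_search(
    incidence: np.ndarray,
    column_classes: list[str],
    params: GabiParams | None = None,
    gene_labels: list[str] | None = None,
    column_labels: list[str] | None = None,
    run_metadata: dict | None = None,
    rng: np.random.Generator | None = None,
) -> list[Bicluster]:
    """Repeated GA searches with tabu masking between emitted biclusters.

    Runs ``amountOfBiclusterSearches`` independent searches; each emits
    at most one bicluster (its best valid candidate), whose qualifying
    cells are then masked to zero in the working incidence matrix for
    the column classes whose ``variableClassNotOnTabuList`` flag is
    False.  Returns possibly fewer biclusters than searches; an empty
    list when nothing meets the support minima.
    """
    params = params or GabiParams()
    n_rows, n_cols = np.asarray(incidence).shape
    gene_labels = gene_labels or [f"g{i}" for i in range(n_rows)]
    column_labels = column_labels or [f"c{j}" for j in range(n_cols)]
    problem = _Problem(incidence, column_classes, gene_labels, column_labels)
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([int(params.seed) & 0x7FFFFFFF]))
    meta = dict(run_metadata or {})
    meta.setdefault("seed", int(params.seed))
    omega_flag, network_flag = params.variableClassNotOnTabuList

    results: list[Bicluster] = []
    for search in range(params.amountOfBiclusterSearches):
        mask = _run_ga(problem, params, rng)
        if mask is None:
            continue
        rows = problem.rows_for_mask(mask, params.row_consistency)
        row_idx = np.flatnonzero(rows)
        sel_net = problem.net_cols[mask]
        genes = frozenset(problem.genes[i] for i in row_idx)
        branches = frozenset(
            _strip_omega_label(problem.columns[j]) for j in problem.omega_cols
        )
        networks = frozenset(problem.columns[j] for j in sel_net)
        sc = _score_counts(len(genes), problem.omega_cols.size, sel_net.size, params)
        results.append(
            Bicluster(
                genes=genes,
                branches=branches,
                networks=networks,
                score=sc,
                run_metadata=tuple(sorted({**meta, "search": search}.items())),
            )
        )
        # tabu: zero the qualifying cells of classes flagged for masking
        if not omega_flag and problem.omega_cols.size:
            problem.inc[np.ix_(row_idx, problem.omega_cols)] = False
        if not network_flag and sel_net.size:
            problem.inc[np.ix_(row_idx, sel_net)] = False
    return results


def _strip_omega_label(label: str) -> str:
    return label.split(":", 1)[1] if label.startswith("omega:") else label


#: Fixed cycling order of the global-optimization parameter combos.
GLOBAL_OPTIM_COMBOS: tuple[tuple[bool, tuple[bool, bool]], ...] = (
    (True, (True, True)),
    (True, (True, False)),
    (False, (True, True)),
    (False, (True, False)),
)


def global_optim_loop(
    incidence: np.ndarray,
    column_classes: list[str],
    params: GabiParams,
    gene_labels: list[str] | None = None,
    column_labels: list[str] | None = None,
) -> list[Bicluster]:
    """Cycle gabi_search through weighting/tabu combos, pooling all results.

    Iteration i of ``params.global_optim`` uses combo i mod 4 of
    :data:`GLOBAL_OPTIM_COMBOS` with a seed derived deterministically
    from the master seed and the iteration index; run metadata records
    the combo.
    """
    if params.global_optim < 1:
        raise ValueError("global_optim must be >= 1 for the optimization loop")
    if params.global_optim % 4 != 0:
        logger.warning(
            "global_optim=%d is not a multiple of 4; combos will be cycled unevenly",
            params.global_optim,
        )
    pooled: list[Bicluster] = []
    for i in range(params.global_optim):
        do_weighting, tabu_flags = GLOBAL_OPTIM_COMBOS[i % 4]
        sub = dataclasses.replace(
            params,
            do_weighting=do_weighting,
            variableClassNotOnTabuList=tabu_flags,
            global_optim=0,
        )
        rng = np.random.default_rng(
            np.random.SeedSequence([int(params.seed) & 0x7FFFFFFF, i])
        )
        meta = {
            "combo": i % 4,
            "iteration": i,
            "do_weighting": do_weighting,
            "variableClassNotOnTabuList": list(tabu_flags),
        }
        pooled.extend(
            gabi_search(
                incidence,
                column_classes,
                sub,
                gene_labels=gene_labels,
                column_labels=column_labels,
                run_metadata=meta,
                rng=rng,
            )
        )
    return pooled


def merge_biclusters(
    biclusters: list[Bicluster],
    overlap_frac: float = 0.5,
    params: GabiParams | None = None,
) -> list[Bicluster]:
    """Merge similar biclusters and recompute their scores (= size).

    Two biclusters are similar when their gene sets overlap by more
    than ``overlap_frac`` of the smaller set, or when their network
    sets are identical.  Connected components of the similarity graph
    are merged by union of genes, branches and networks; the pass is
    repeated until nothing changes, so the result is a fixed point of
    the rule (idempotent).
    """
    params = params or GabiParams()
    items = list(biclusters)
    while True:
        merged = _merge_pass(items, overlap_frac, params)
        if len(merged) == len(items):
            return merged
        items = merged


def _similar(a: Bicluster, b: Bicluster, overlap_frac: float) -> bool:
    if a.networks == b.networks:
        return True
    smaller = min(len(a.genes), len(b.genes))
    if smaller == 0:
        return False
    return len(a.genes & b.genes) / smaller > overlap_frac


def _merge_pass(
    items: list[Bicluster], overlap_frac: float, params: GabiParams
) -> list[Bicluster]:
    n = len(items)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if _similar(items[i], items[j], overlap_frac):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    out: list[Bicluster] = []
    for root in sorted(groups):
        members = groups[root]
        if len(members) == 1:
            out.append(items[members[0]])
            continue
        genes = frozenset().union(*(items[i].genes for i in members))
        branches = frozenset().union(*(items[i].branches for i in members))
        networks = frozenset().union(*(items[i].networks for i in members))
        sc = _score_counts(len(genes), len(branches), len(networks), params)
        out.append(
            Bicluster(
                genes=genes,
                branches=branches,
                networks=networks,
                score=sc,
                run_metadata=(("merged_from", len(members)),),
            )
        )
    return out
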