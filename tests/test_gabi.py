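"""Genetic-algorithm biclustering: thresholds, search, tabu, merging.

Small instances are checked against an exhaustive column-subset
enumeration oracle; planted-block recovery is assessed over seeds.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from evoselect.datatypes import AnalysisMatrix, Bicluster
from evoselect.gabi import (
    GLOBAL_OPTIM_COMBOS,
    GabiParams,
    ThresholdSpec,
    binarize,
    branch_thresholds,
    gabi_search,
    global_optim_loop,
    merge_biclusters,
    score,
)
from evoselect.prep import GenePools, NormalizedOmega


def exhaustive_best_score(incidence, column_classes, params):
    """Enumerate every network-column subset; the independent optimum oracle."""
    incidence = np.asarray(incidence, dtype=bool)
    net_cols = [j for j, c in enumerate(column_classes) if c == "network"]
    omega_cols = [j for j, c in enumerate(column_classes) if c == "omega"]
    omega_ok = incidence[:, omega_cols].all(axis=1) if omega_cols else np.ones(
        incidence.shape[0], dtype=bool
    )
    best = 0.0
    for k in range(params.min_network_cols, len(net_cols) + 1):
        for subset in itertools.combinations(net_cols, k):
            rows = incidence[:, list(subset)].all(axis=1) & omega_ok
            n_genes = int(rows.sum())
            if n_genes < params.min_genes:
                continue
            if params.do_weighting:
                s = n_genes * (params.weight_omega * len(omega_cols) + params.weight_network * k)
            else:
                s = n_genes * (len(omega_cols) + k)
            best = max(best, float(s))
    return best


def planted_incidence(rng, n_rows=500, n_net=20, block_rows=50, block_cols=4, density=0.05):
    """Sparse background with one planted all-ones block (omega col + networks)."""
    inc = rng.random((n_rows, n_net + 1)) < density
    classes = ["omega"] + ["network"] * n_net
    rows = np.arange(block_rows)
    cols = np.concatenate([[0], 1 + np.arange(block_cols)])
    inc[np.ix_(rows, cols)] = True
    return inc, classes, set(f"g{i}" for i in rows), set(f"c{j}" for j in cols[1:])


class TestThresholds:
    @staticmethod
    def setup_pools():
        genes = [f"g{i}" for i in range(6)]
        values = np.array([[0.2], [0.4], [0.6], [0.8], [0.93], [1.0]])
        onorm = NormalizedOmega(genes, ["b0"], values)
        pools = GenePools(high={"b0": ["g4", "g5"]}, low={"b0": ["g0", "g1"]})
        return onorm, pools

    def test_high_direction_uses_pool_minimum(self):
        onorm, pools = self.setup_pools()
        spec = branch_thresholds(onorm, pools, "b0", "high")
        assert spec.omega_lo == pytest.approx(0.93)
        assert spec.omega_hi == np.inf

    def test_low_direction_uses_pool_maximum(self):
        onorm, pools = self.setup_pools()
        spec = branch_thresholds(onorm, pools, "b0", "low")
        assert spec.omega_hi == pytest.approx(0.4)
        assert spec.omega_lo == -np.inf

    def test_branch_specific_thresholds_differ(self):
        genes = [f"g{i}" for i in range(4)]
        values = np.array([[0.25, 0.5], [0.5, 0.75], [0.75, 1.0], [1.0, 0.25]])
        onorm = NormalizedOmega(genes, ["b0", "b1"], values)
        pools = GenePools(high={"b0": ["g3"], "b1": ["g2"]}, low={"b0": [], "b1": []})
        lo0 = branch_thresholds(onorm, pools, "b0", "high").omega_lo
        lo1 = branch_thresholds(onorm, pools, "b1", "high").omega_lo
        assert lo0 == pytest.approx(1.0) and lo1 == pytest.approx(1.0)
        assert branch_thresholds(onorm, pools, "b0", "high").omega_lo == lo0

    def test_empty_pool_rejected(self):
        onorm, pools = self.setup_pools()
        pools.high["b0"] = []
        with pytest.raises(ValueError, match="empty"):
            branch_thresholds(onorm, pools, "b0", "high")


class TestBinarize:
    @staticmethod
    def matrix(values):
        values = np.atleast_2d(values)
        classes = ["omega"] + ["network"] * (values.shape[1] - 1)
        return AnalysisMatrix(
            [f"g{i}" for i in range(values.shape[0])],
            ["omega:b"] + [f"n{j}" for j in range(values.shape[1] - 1)],
            values,
            column_classes=classes,
        )

    def test_all_above_thresholds(self):
        m = self.matrix(np.full((3, 4), 0.9))
        inc = binarize(m, ThresholdSpec(omega_lo=0.5))
        assert inc.all()

    def test_missing_cell_never_qualifies(self):
        vals = np.full((2, 3), 0.9)
        vals[0, 1] = np.nan
        inc = binarize(self.matrix(vals), ThresholdSpec())
        assert not inc[0, 1] and inc[1, 1]

    def test_network_boundary_inclusive(self):
        vals = np.array([[0.9, 0.75, 0.74999]])
        inc = binarize(self.matrix(vals), ThresholdSpec(network_min=0.75))
        assert inc[0, 1] and not inc[0, 2]

    def test_omega_window_inclusive(self):
        vals = np.array([[0.5, 0.9], [0.49999, 0.9]])
        inc = binarize(self.matrix(vals), ThresholdSpec(omega_lo=0.5))
        assert inc[0, 0] and not inc[1, 0]


class TestScore:
    def test_unweighted_is_area(self):
        b = Bicluster(frozenset("abc"), frozenset({"b0"}), frozenset({"n1", "n2"}), 9.0)
        assert score(b) == 9.0

    def test_weighted_uses_class_weights(self):
        b = Bicluster(frozenset("abc"), frozenset({"b0"}), frozenset({"n1"}), 0.0)
        assert score(b, GabiParams(do_weighting=True)) == 3 * (2 + 1)


class TestGabiSearch:
    def test_all_zero_incidence_gives_empty_list(self):
        inc = np.zeros((20, 5), dtype=bool)
        out = gabi_search(inc, ["omega"] + ["network"] * 4, GabiParams(
            amountOfBiclusterSearches=2, popsize=20, generations=10, seed=1
        ))
        assert out == []

    def test_all_ones_recovers_entire_matrix(self):
        inc = np.ones((50, 10), dtype=bool)
        classes = ["omega"] + ["network"] * 9
        params = GabiParams(
            amountOfBiclusterSearches=1, popsize=40, generations=60, seed=3
        )
        out = gabi_search(inc, classes, params)
        assert len(out) == 1
        b = out[0]
        assert len(b.genes) == 50 and len(b.networks) == 9
        assert b.score == 500.0

    def test_membership_constraint_holds(self, rng):
        inc = rng.random((80, 9)) < 0.4
        inc[:, 0] |= rng.random(80) < 0.5
        classes = ["omega"] + ["network"] * 8
        gene_labels = [f"g{i}" for i in range(80)]
        col_labels = ["omega:b"] + [f"n{j}" for j in range(8)]
        params = GabiParams(amountOfBiclusterSearches=3, popsize=40, generations=30, seed=5)
        pre_tabu = inc.copy()
        out = gabi_search(inc, classes, params, gene_labels, col_labels)
        for b in out:
            rows = [gene_labels.index(g) for g in b.genes]
            cols = [0] + [col_labels.index(n) for n in b.networks]
            assert pre_tabu[np.ix_(rows, cols)].all()

    def test_matches_exhaustive_oracle_on_small_instances(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            inc = rng.random((60, 10)) < 0.35
            classes = ["omega"] + ["network"] * 9
            params = GabiParams(
                amountOfBiclusterSearches=3, popsize=60, generations=40, seed=seed
            )
            out = gabi_search(inc, classes, params)
            best_found = max((b.score for b in out), default=0.0)
            assert best_found <= exhaustive_best_score(inc, classes, params) + 1e-9
            if best_found == exhaustive_best_score(inc, classes, params):
                hits += 1
        assert hits >= 8

    def test_planted_block_recovered(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(2000 + seed)
            inc, classes, true_genes, true_nets = planted_incidence(rng)
            params = GabiParams(
                amountOfBiclusterSearches=3, popsize=100, generations=60, seed=seed
            )
            out = gabi_search(inc, classes, params)
            best = max(out, key=lambda b: b.score)
            jac = len(best.genes & true_genes) / len(best.genes | true_genes)
            if jac >= 0.9:
                hits += 1
        assert hits >= 4

    def test_tabu_masks_shared_network_cells(self, rng):
        inc = rng.random((100, 11)) < 0.45
        inc[:, 0] = True
        classes = ["omega"] + ["network"] * 10
        gene_labels = [f"g{i}" for i in range(100)]
        col_labels = ["omega:b"] + [f"n{j}" for j in range(10)]
        params = GabiParams(
            amountOfBiclusterSearches=4,
            popsize=60,
            generations=40,
            variableClassNotOnTabuList=(True, False),  # networks masked
            seed=9,
        )
        out = gabi_search(inc, classes, params, gene_labels, col_labels)
        assert len(out) >= 2
        for a, b in itertools.combinations(out, 2):
            shared = {
                (g, n) for g in a.genes & b.genes for n in a.networks & b.networks
            }
            assert not shared

    def test_deterministic_under_fixed_seed(self, rng):
        inc = rng.random((60, 8)) < 0.4
        classes = ["omega"] + ["network"] * 7
        params = GabiParams(amountOfBiclusterSearches=2, popsize=40, generations=20, seed=11)
        assert gabi_search(inc, classes, params) == gabi_search(inc, classes, params)


class TestGlobalOptim:
    def test_iterations_cycle_combos(self, rng):
        inc = rng.random((60, 8)) < 0.5
        inc[:, 0] = True
        classes = ["omega"] + ["network"] * 7
        params = GabiParams(
            amountOfBiclusterSearches=1, popsize=30, generations=15, global_optim=4, seed=2
        )
        out = global_optim_loop(inc, classes, params)
        combos_seen = {b.meta["combo"] for b in out}
        assert combos_seen <= {0, 1, 2, 3}
        assert len({b.meta["iteration"] for b in out}) == len(
            {i for i in range(4) if any(b.meta["iteration"] == i for b in out)}
        )

    def test_eight_iterations_visit_each_combo_twice(self, rng):
        inc = rng.random((40, 6)) < 0.6
        inc[:, 0] = True
        classes = ["omega"] + ["network"] * 5
        params = GabiParams(
            amountOfBiclusterSearches=1, popsize=24, generations=10, global_optim=8, seed=4
        )
        out = global_optim_loop(inc, classes, params)
        iters = sorted({b.meta["iteration"] for b in out})
        for i in iters:
            assert GLOBAL_OPTIM_COMBOS[i % 4][0] == [b for b in out if b.meta["iteration"] == i][0].meta["do_weighting"]

    def test_reproducible_for_fixed_master_seed(self, rng):
        inc = rng.random((40, 6)) < 0.5
        inc[:, 0] = True
        classes = ["omega"] + ["network"] * 5
        params = GabiParams(
            amountOfBiclusterSearches=1, popsize=24, generations=10, global_optim=4, seed=6
        )
        assert global_optim_loop(inc, classes, params) == global_optim_loop(inc, classes, params)


class TestMerge:
    @staticmethod
    def bic(genes, networks, branches=("b0",)):
        b = Bicluster(frozenset(genes), frozenset(branches), frozenset(networks), 1.0)
        return Bicluster(b.genes, b.branches, b.networks, score(b))

    def test_overlap_rule_merges(self):
        a = self.bic([f"g{i}" for i in range(10)], ["n1"])
        b = self.bic([f"g{i}" for i in range(5, 13)], ["n2"])  # 5 shared / min 8 = 0.625
        merged = merge_biclusters([a, b])
        assert len(merged) == 1
        assert len(merged[0].genes) == 13
        assert merged[0].score == 13 * (1 + 2)

    def test_same_networks_always_merge(self):
        a = self.bic(["g1", "g2"], ["n1", "n2"])
        b = self.bic(["g8", "g9"], ["n1", "n2"])
        assert len(merge_biclusters([a, b])) == 1

    def test_dissimilar_kept_apart(self):
        a = self.bic(["g1", "g2"], ["n1"])
        b = self.bic(["g8", "g9"], ["n2"])
        assert len(merge_biclusters([a, b])) == 2

    def test_boundary_overlap_not_merged(self):
        # exactly 50% of the smaller set: rule requires strictly more
        a = self.bic(["g1", "g2", "g3", "g4"], ["n1"])
        b = self.bic(["g3", "g4", "g9", "g10"], ["n2"])
        assert len(merge_biclusters([a, b])) == 2

    def test_idempotent(self, rng):
        bics = []
        for i in range(12):
            genes = [f"g{j}" for j in rng.choice(40, size=rng.integers(4, 12), replace=False)]
            nets = [f"n{j}" for j in rng.choice(6, size=rng.integers(1, 4), replace=False)]
            bics.append(self.bic(genes, nets))
        once = merge_biclusters(bics)
        twice = merge_biclusters(once)
        assert once == twice

    def test_transitive_chains_collapse(self):
        a = self.bic([f"g{i}" for i in range(8)], ["n1"])
        b = self.bic([f"g{i}" for i in range(3, 11)], ["n2"])  # 5/8 with a
        c = self.bic([f"g{i}" for i in range(6, 14)], ["n3"])  # 5/8 with b, 2/8 with a
        merged = merge_biclusters([a, c, b])
        assert len(merged) == 1
        assert len(merged[0].genes) == 14
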