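"""Constraint handling, rank normalizations, gene pools, concatenation.

Both rank normalizations are checked against brute-force evaluations
of their defining count formulas (competition/minimum ties for omega,
maximum ties for correlations) on randomized matrices with ties,
zeros and missing cells.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from evoselect.datatypes import CorrelationMatrix, OmegaTable
from evoselect.prep import (
    apply_omega_constraints,
    build_gene_pools,
    concatenate,
    filter_spatial_genes,
    rank_normalize_correlations,
    rank_normalize_omega,
)


def omega_rank_oracle(col):
    """Literal count evaluation: (1 + #{k != i: w_k < w_i}) / #{k: w_k > 0}."""
    col = np.asarray(col, dtype=float)
    present = np.isfinite(col)
    denom = int(((col > 0) & present).sum())
    out = np.full(col.shape, np.nan)
    if denom == 0:
        return out
    for i in np.flatnonzero(present):
        smaller = int((col[present] < col[i]).sum())
        out[i] = (1 + smaller) / denom
    return out


def corr_rank_oracle(row, n_networks):
    """Literal max-tie rank: #{k: r_k <= r_j} / |n| over present entries."""
    row = np.asarray(row, dtype=float)
    present = np.isfinite(row)
    out = np.zeros(row.shape)
    for j in np.flatnonzero(present):
        out[j] = int((row[present] <= row[j]).sum()) / n_networks
    return out


def make_omega(values, status=None, branches=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    genes = [f"g{i}" for i in range(values.shape[0])]
    branches = branches or [f"b{j}" for j in range(values.shape[1])]
    return OmegaTable(genes, branches, values, status=status)


class TestOmegaConstraints:
    @staticmethod
    def table():
        values = np.array(
            [[2.7, 0.3], [1.2, np.nan], [np.nan, 0.5], [np.nan, np.nan], [0.0, np.nan], [np.nan, np.nan]]
        )
        status = np.array(
            [
                ["STABLE", "STABLE"],
                ["STABLE", "UNSTABLE"],
                ["DS_ZERO", "STABLE"],
                ["DN_ZERO", "SHORT_EDGE_UNSTABLE"],
                ["STABLE", "IDENTICAL"],
                ["UNSTABLE", "DS_ZERO"],
            ],
            dtype=object,
        )
        return make_omega(values, status=status)

    def test_relaxed_recodes_degenerate_outcomes(self):
        out = apply_omega_constraints(self.table(), "relaxed")
        # dS = 0 -> maximum retained omega of the branch
        assert out.values[2, 0] == pytest.approx(2.7)
        assert out.values[5, 1] == pytest.approx(0.5)
        # dN = 0 -> 0 (purifying); identical sequences -> 0 (neutral)
        assert out.values[3, 0] == 0.0
        assert out.values[4, 1] == 0.0
        # unstable estimates always dropped
        assert np.isnan(out.values[1, 1]) and np.isnan(out.values[3, 1])
        assert np.isnan(out.values[5, 0])

    def test_conservative_drops_degenerate_outcomes(self):
        out = apply_omega_constraints(self.table(), "conservative")
        for i, j in [(2, 0), (3, 0), (4, 1), (5, 1)]:
            if self.table().status[i, j] in ("DN_ZERO", "DS_ZERO", "IDENTICAL"):
                assert np.isnan(out.values[i, j])

    def test_conservative_cells_subset_of_relaxed(self, rng):
        codes = np.array(
            ["STABLE", "UNSTABLE", "SHORT_EDGE_UNSTABLE", "DN_ZERO", "DS_ZERO", "IDENTICAL"],
            dtype=object,
        )
        status = rng.choice(codes, size=(30, 4))
        values = rng.exponential(0.5, size=(30, 4))
        values[np.isin(status, ["UNSTABLE", "SHORT_EDGE_UNSTABLE", "DN_ZERO", "DS_ZERO", "IDENTICAL"])] = np.nan
        table = make_omega(values, status=status)
        cons = np.isfinite(apply_omega_constraints(table, "conservative").values)
        relax = np.isfinite(apply_omega_constraints(table, "relaxed").values)
        assert np.all(relax[cons])  # conservative non-missing ⊆ relaxed non-missing

    def test_unknown_status_rejected(self):
        from evoselect.datatypes import FormatError

        with pytest.raises(FormatError, match="unknown"):
            make_omega([[1.0]], status=np.array([["WEIRD"]], dtype=object))


class TestRankNormalizeOmega:
    def test_branch_maximum_maps_to_one(self, rng):
        col = rng.permutation(np.linspace(0.1, 3.0, 20))
        norm = rank_normalize_omega(make_omega(col[:, None]))
        assert norm.values[np.argmax(col), 0] == pytest.approx(1.0)

    def test_two_positive_values(self):
        norm = rank_normalize_omega(make_omega(np.array([[0.5], [2.0]])))
        np.testing.assert_allclose(norm.values[:, 0], [0.5, 1.0])

    @pytest.mark.parametrize("trial", range(8))
    def test_ties_zeros_missing_match_count_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        col = rng.choice([0.0, 0.0, 0.3, 0.3, 1.1, 2.5, np.nan], size=25)
        norm = rank_normalize_omega(make_omega(col[:, None]))
        np.testing.assert_allclose(
            norm.values[:, 0], omega_rank_oracle(col), equal_nan=True, rtol=1e-12
        )

    def test_all_zero_branch_becomes_missing(self):
        norm = rank_normalize_omega(make_omega(np.array([[0.0], [0.0]])))
        assert np.isnan(norm.values).all()

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        st.lists(
            st.one_of(
                st.floats(min_value=0.0, max_value=10.0, allow_nan=False),
                st.just(float("nan")),
            ),
            min_size=2,
            max_size=15,
        )
    )
    def test_order_preserving(self, values):
        col = np.array(values)
        norm = rank_normalize_omega(make_omega(col[:, None])).values[:, 0]
        present = np.isfinite(col)
        idx = np.flatnonzero(present)
        if not np.isfinite(norm[idx]).all():
            return  # no positive entries: whole branch missing by design
        for a in idx:
            for b in idx:
                if col[a] < col[b]:
                    assert norm[a] <= norm[b]


class TestGenePools:
    def test_threshold_counts(self):
        table = make_omega(np.array([[0.0], [0.2], [1.5], [3.0]]))
        pools = build_gene_pools(table, harmonize=False)
        assert set(pools.high["b0"]) == {"g2", "g3"}
        assert pools.low["b0"] == ["g0"]

    def test_harmonization_truncates_to_minimum(self, rng):
        values = np.column_stack(
            [
                np.concatenate([rng.uniform(1.1, 3.0, 40), rng.uniform(0.0, 0.9, 60)]),
                np.concatenate([rng.uniform(1.1, 3.0, 25), rng.uniform(0.0, 0.9, 75)]),
            ]
        )
        # guarantee low pools exist in both branches
        values[95:, :] = 0.0
        table = make_omega(values)
        pools = build_gene_pools(table, harmonize=True)
        assert len(pools.high["b0"]) == len(pools.high["b1"]) == 25
        # truncation keeps the largest-omega genes
        kept = [table.genes.index(g) for g in pools.high["b0"]]
        dropped = sorted(set(range(40)) - set(kept))
        assert min(values[kept, 0]) >= max(values[dropped, 0]) - 1e-12

    def test_harmonize_equal_sizes_is_identity(self, rng):
        values = np.column_stack([rng.uniform(1.1, 2.0, 10), rng.uniform(1.1, 2.0, 10)])
        values[8:] = 0.0
        table = make_omega(values)
        assert build_gene_pools(table, harmonize=True).high == build_gene_pools(table, harmonize=False).high

    def test_empty_pool_names_branch(self):
        table = make_omega(np.array([[0.5, 1.5], [0.0, 2.0]]), branches=["AMH", "Chimp"])
        with pytest.raises(ValueError, match="AMH"):
            build_gene_pools(table)


class TestSpatialFilter:
    @staticmethod
    def corr(vals):
        vals = np.atleast_2d(vals)
        return CorrelationMatrix(
            [f"n{i}" for i in range(vals.shape[0])],
            [f"g{j}" for j in range(vals.shape[1])],
            vals,
        )

    def test_gene_below_threshold_everywhere_excluded(self):
        r = self.corr(np.array([[0.05, 0.5], [-0.09, 0.3]]))
        assert filter_spatial_genes(r, 0.1) == {"g1"}

    def test_negative_correlation_counts_by_default(self):
        r = self.corr(np.array([[-0.5], [0.02]]))
        assert filter_spatial_genes(r, 0.1) == {"g0"}
        assert filter_spatial_genes(r, 0.1, use_absolute=False) == set()

    def test_zero_threshold_keeps_any_nonzero(self):
        r = self.corr(np.array([[0.0, 0.001]]))
        assert filter_spatial_genes(r, 0.0) == {"g1"}


class TestRankNormalizeCorrelations:
    @staticmethod
    def corr(vals):
        vals = np.atleast_2d(vals)  # network x gene
        return CorrelationMatrix(
            [f"n{i}" for i in range(vals.shape[0])],
            [f"g{j}" for j in range(vals.shape[1])],
            vals,
        )

    def test_top_network_maps_to_one(self, rng):
        vals = rng.uniform(-0.8, 0.8, size=(7, 4))
        norm = rank_normalize_correlations(self.corr(vals))
        for g in range(4):
            assert norm.values[g, np.argmax(vals[:, g])] == pytest.approx(1.0)

    def test_low_overall_gene_row_is_zeroed(self):
        vals = np.array([[0.05, 0.5], [-0.08, 0.6], [0.01, 0.7]])
        norm = rank_normalize_correlations(self.corr(vals))
        np.testing.assert_array_equal(norm.values[0], 0.0)
        assert norm.values[1].max() == pytest.approx(1.0)

    def test_three_network_distinct_values(self):
        vals = np.array([[0.2], [0.4], [0.6]])
        # ranks 1, 2, 3 over |n| = 3 -> 1/3, 2/3, 1; minimum then zeroed
        norm = rank_normalize_correlations(self.corr(vals))
        np.testing.assert_allclose(norm.values[0], [0.0, 2 / 3, 1.0])
        pre = rank_normalize_correlations(self.corr(vals), zero_minimum=False)
        np.testing.assert_allclose(pre.values[0], [1 / 3, 2 / 3, 1.0])

    @pytest.mark.parametrize("trial", range(8))
    def test_ties_and_missing_match_count_oracle(self, trial):
        rng = np.random.default_rng(300 + trial)
        vals = rng.choice([-0.5, -0.2, 0.2, 0.2, 0.6, 0.6, np.nan], size=(9, 6))
        r = self.corr(vals)
        norm = rank_normalize_correlations(r, low_corr_cut=0.0, zero_minimum=False)
        for g in range(6):
            np.testing.assert_allclose(
                norm.values[g], corr_rank_oracle(vals[:, g], 9), rtol=1e-12
            )

    def test_monotone_transform_invariance(self, rng):
        vals = rng.uniform(0.15, 0.9, size=(8, 3))
        r1 = rank_normalize_correlations(self.corr(vals))
        r2 = rank_normalize_correlations(self.corr(np.tanh(3 * vals)))
        np.testing.assert_allclose(r1.values, r2.values)

    def test_minimum_zeroed_per_gene(self, rng):
        vals = rng.uniform(0.15, 0.9, size=(6, 5))
        norm = rank_normalize_correlations(self.corr(vals))
        assert (norm.values.min(axis=1) == 0.0).all()

    def test_retained_flag_on_normalized_rows(self):
        vals = np.array([[0.2, 0.3], [0.5, 0.31], [0.6, 0.32], [0.65, 0.33]])
        norm = rank_normalize_correlations(self.corr(vals), gene_filter_cut=0.75)
        # every gene's top network reaches 1 >= 0.75 -> retained
        assert norm.retained.all()
        raw = rank_normalize_correlations(
            self.corr(vals), gene_filter_cut=0.5, filter_on_normalized=False
        )
        assert raw.retained.tolist() == [True, False]


class TestConcatenate:
    def test_shape_and_column_classes(self, rng):
        from evoselect.prep import rank_normalize_omega

        omega = make_omega(rng.uniform(0.1, 3.0, size=(10, 2)))
        onorm = rank_normalize_omega(omega)
        r = TestRankNormalizeCorrelations.corr(rng.uniform(0.2, 0.9, size=(4, 10)))
        rnorm = rank_normalize_correlations(r)
        m = concatenate(onorm, "b0", rnorm)
        assert m.shape == (10, 5)
        assert m.column_classes == ["omega"] + ["network"] * 4
        assert m.col_labels[0] == "omega:b0"

    def test_gene_missing_omega_dropped(self, rng):
        from evoselect.prep import rank_normalize_omega

        vals = rng.uniform(0.1, 3.0, size=(5, 1))
        vals[2, 0] = np.nan
        onorm = rank_normalize_omega(make_omega(vals))
        r = TestRankNormalizeCorrelations.corr(rng.uniform(0.2, 0.9, size=(3, 5)))
        rnorm = rank_normalize_correlations(r)
        m = concatenate(onorm, "b0", rnorm)
        assert "g2" not in m.genes and len(m.genes) == 4

    def test_empty_intersection_rejected(self, rng):
        from evoselect.prep import rank_normalize_omega

        onorm = rank_normalize_omega(make_omega(np.full((3, 1), np.nan)))
        r = TestRankNormalizeCorrelations.corr(rng.uniform(0.2, 0.9, size=(3, 3)))
        rnorm = rank_normalize_correlations(r)
        with pytest.raises(ValueError, match="no genes"):
            concatenate(onorm, "b0", rnorm)
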