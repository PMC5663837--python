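"""Expression formulas, presence/Manhattan heterogeneity, clustering, correlation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from circkit.errors import ConfigurationError, DomainError
from circkit.quantify import (
    CellFeatureMatrix,
    compute_cgr,
    compute_circ_fpkm,
    hierarchical_cluster,
    manhattan_distances,
    pearson_correlation,
    presence_matrix,
)


class TestFormulas:
    @pytest.mark.parametrize(
        "jr,host,expected", [(5, 50, 0.1), (0, 50, 0.0), (1, 3, 1 / 3)]
    )
    def test_cgr_is_the_exact_quotient(self, jr, host, expected):
        assert compute_cgr(jr, host) == pytest.approx(expected, abs=1e-15)

    def test_cgr_zero_host_reads_is_na(self):
        assert math.isnan(compute_cgr(3, 0))

    @pytest.mark.parametrize(
        "jr,mm,hf,expected", [(10, 2.0, 5.0, 1.0), (0, 2.0, 5.0, 0.0), (7, 2.0, 0.5, 7.0)]
    )
    def test_circ_fpkm_normalizes_by_library_and_host(self, jr, mm, hf, expected):
        assert compute_circ_fpkm(jr, mm, hf) == pytest.approx(expected, abs=1e-15)

    def test_circ_fpkm_zero_denominator_is_na(self):
        assert math.isnan(compute_circ_fpkm(10, 1.0, 0.0))
        assert math.isnan(compute_circ_fpkm(10, 0.0, 1.0))

    def test_negative_inputs_are_domain_errors(self):
        with pytest.raises(DomainError):
            compute_cgr(-1, 5)
        with pytest.raises(DomainError):
            compute_circ_fpkm(1, -2.0, 1.0)

    def test_quantities_scale_linearly_in_junction_reads(self):
        assert compute_cgr(10, 50) == 2 * compute_cgr(5, 50)
        assert compute_circ_fpkm(20, 2.0, 5.0) == 4 * compute_circ_fpkm(5, 2.0, 5.0)


class TestPresenceMatrix:
    def test_two_cell_example(self, minimal):
        from circkit.consensus import intersect_calls

        pm = presence_matrix(intersect_calls(minimal.calls), minimal.cells)
        pd.testing.assert_frame_equal(pm.to_frame(), minimal.expected_presence)

    def test_cell_with_no_circrnas_gets_all_zero_row(self, minimal):
        from circkit.consensus import intersect_calls

        cons = intersect_calls(minimal.calls)
        pm = presence_matrix(cons, minimal.cells + ["cell_empty"])
        assert pm.to_frame().loc["cell_empty"].sum() == 0

    def test_presence_matrix_rejects_non_binary(self):
        with pytest.raises(ValueError):
            CellFeatureMatrix(["a"], ["f"], np.array([[0.5]]), kind="presence")


class TestManhattan:
    def test_single_discordant_feature(self):
        m = CellFeatureMatrix(["a", "b"], list("xyz"), np.array([[1, 0, 1], [0, 0, 1]]))
        assert manhattan_distances(m).loc["a", "b"] == 1.0

    def test_identical_rows_have_zero_distance(self):
        m = CellFeatureMatrix(["a", "b"], list("xyz"), np.ones((2, 3)))
        assert manhattan_distances(m).loc["a", "b"] == 0.0

    def test_fixture_distances_match_hand_table(self, minimal):
        from circkit.consensus import intersect_calls

        pm = presence_matrix(intersect_calls(minimal.calls), minimal.cells)
        pd.testing.assert_frame_equal(manhattan_distances(pm), minimal.expected_manhattan)

    def test_equals_brute_force_discordance_count(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            vals = (rng.random((8, 20)) < 0.4).astype(float)
            m = CellFeatureMatrix([f"c{i}" for i in range(8)],
                                  [f"f{j}" for j in range(20)], vals)
            d = manhattan_distances(m).to_numpy()
            for i in range(8):
                for j in range(8):
                    assert d[i, j] == np.sum(vals[i] != vals[j])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(arrays(float, (5, 9), elements=st.sampled_from([0.0, 1.0])))
    def test_metric_axioms_on_binary_matrices(self, vals):
        m = CellFeatureMatrix([f"c{i}" for i in range(5)],
                              [f"f{j}" for j in range(9)], vals)
        d = manhattan_distances(m).to_numpy()
        assert np.allclose(d, d.T) and np.all(np.diag(d) == 0) and np.all(d >= 0)
        for i in range(5):
            for j in range(5):
                for k in range(5):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestHierarchicalCluster:
    def test_identical_pair_merges_first_at_height_zero(self):
        vals = np.array([[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1]], dtype=float)
        m = CellFeatureMatrix(["a", "b", "c"], list("wxyz"), vals)
        dend = hierarchical_cluster(m, linkage="complete", metric="manhattan")
        assert dend.linkage[0, 2] == 0.0
        assert sorted(dend.linkage[0, :2]) == [0, 1]  # cells a and b

    def test_three_cell_complete_linkage_matches_hand_agglomeration(self):
        # pairwise Manhattan: d(a,b)=1, d(a,c)=3, d(b,c)=2
        vals = np.array([[1, 1, 1, 0], [1, 1, 0, 0], [0, 1, 0, 1]], dtype=float)
        m = CellFeatureMatrix(["a", "b", "c"], list("wxyz"), vals)
        dend = hierarchical_cluster(m, linkage="complete", metric="manhattan")
        # first merge: (a,b) at 1; then c joins at max(d(a,c), d(b,c)) = 3
        assert dend.merge_heights() == [1.0, 3.0]

    def test_tree_topology_invariant_to_cell_order(self):
        # continuous values so pairwise distances are distinct (no tie ambiguity)
        rng = np.random.default_rng(4)
        vals = rng.random((6, 15))
        cells = [f"c{i}" for i in range(6)]
        feats = [f"f{j}" for j in range(15)]

        def clades(m):
            dend = hierarchical_cluster(m, "average", "manhattan")
            from scipy.cluster.hierarchy import to_tree

            out = set()

            def walk(node):
                if node.is_leaf():
                    return frozenset([m.cells[node.id]])
                s = walk(node.left) | walk(node.right)
                out.add(s)
                return s

            walk(to_tree(dend.linkage))
            return out

        perm = rng.permutation(6)
        m1 = CellFeatureMatrix(cells, feats, vals, kind="expression")
        m2 = CellFeatureMatrix([cells[i] for i in perm], feats, vals[perm], kind="expression")
        assert clades(m1) == clades(m2)

    def test_fewer_than_two_cells_is_an_error(self):
        m = CellFeatureMatrix(["a"], ["x"], np.array([[1.0]]))
        with pytest.raises(DomainError):
            hierarchical_cluster(m)

    def test_ward_requires_euclidean(self):
        m = CellFeatureMatrix(["a", "b"], ["x"], np.array([[1.0], [0.0]]))
        with pytest.raises(ConfigurationError):
            hierarchical_cluster(m, linkage="ward", metric="manhattan")

    def test_newick_export_contains_all_leaves(self):
        vals = np.array([[1, 0], [0, 1], [1, 1]], dtype=float)
        m = CellFeatureMatrix(["a", "b", "c"], ["x", "y"], vals)
        nwk = hierarchical_cluster(m).to_newick()
        assert nwk.endswith(";") and all(c in nwk for c in "abc")


class TestPearson:
    def test_perfect_positive_and_negative(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        assert pearson_correlation(x, x)[0] == pytest.approx(1.0)
        assert pearson_correlation(x, -x)[0] == pytest.approx(-1.0)

    def test_nan_pairs_are_dropped(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = np.array([2.0, 4.0, 100.0, 8.0, np.nan])
        r, _ = pearson_correlation(x, y)
        assert r == pytest.approx(1.0)

    def test_too_few_pairs_is_domain_error(self):
        with pytest.raises(DomainError):
            pearson_correlation([1.0, 2.0], [1.0, 2.0])

    @pytest.mark.parametrize("n", [200, 2000])
    def test_recovers_generator_correlation(self, n):
        """Estimated r approaches the simulated coupling as n grows."""
        rng = np.random.default_rng(n)
        target = -0.8
        cov = [[1, target], [target, 1]]
        z = rng.multivariate_normal([0, 0], cov, size=n)
        r, p = pearson_correlation(z[:, 0], z[:, 1])
        tol = 0.1 if n == 200 else 0.04
        assert abs(r - target) < tol
        assert p < 1e-6

    def test_log10_pairing_drops_nonpositive(self):
        x = np.array([10.0, 100.0, 1000.0, 0.0, 10.0**4])
        y = np.array([10.0, 100.0, 1000.0, 7.0, 10.0**4])
        r, _ = pearson_correlation(x, y, pairing="log10")
        assert r == pytest.approx(1.0)
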