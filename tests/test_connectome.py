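import numpy as np
import pytest

from conftest import toy_feature_matrix
from morphconn.connectome import (
    BinaryNetwork,
    ConnectivityMatrix,
    absolute_matrix,
    binarize_at_sparsity,
    check_no_isolated_nodes,
    feature_correlation_matrix,
    round_half_up,
    sparsity_grid,
    sparsity_sweep,
)
from morphconn.features import zscore_features
from oracles import pearson_oracle


def abs_matrix_from(values, regions=None):
    values = np.asarray(values, dtype=float)
    regions = regions or tuple(f"r{i}" for i in range(values.shape[0]))
    return ConnectivityMatrix(values=values, regions=tuple(regions), absolute=True)


class TestCorrelation:
    def test_identical_vectors_r_one(self):
        v = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [0.0, 1.0, 0.0]])
        c = feature_correlation_matrix(toy_feature_matrix(v))
        assert c.values[0, 1] == pytest.approx(1.0)

    def test_opposite_vectors_r_minus_one(self):
        v = np.array([[1.0, 0.0, -1.0], [-1.0, 0.0, 1.0], [0.0, 2.0, 1.0]])
        c = feature_correlation_matrix(toy_feature_matrix(v))
        assert c.values[0, 1] == pytest.approx(-1.0)

    def test_matches_textbook_formula_elementwise(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=(6, 7))
        c = feature_correlation_matrix(toy_feature_matrix(values))
        for i in range(6):
            for j in range(i + 1, 6):
                assert c.values[i, j] == pytest.approx(
                    pearson_oracle(values[i], values[j]), abs=1e-12
                )

    def test_constant_region_vector_named(self):
        values = np.random.default_rng(0).normal(size=(4, 5))
        values[2] = 3.0
        with pytest.raises(ValueError, match="r2"):
            feature_correlation_matrix(toy_feature_matrix(values))

    def test_fewer_than_three_features_rejected(self):
        with pytest.raises(ValueError, match="3 features"):
            feature_correlation_matrix(toy_feature_matrix(np.eye(4)[:, :2] + 0.1))

    def test_region_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        values = rng.normal(size=(8, 5))
        perm = rng.permutation(8)
        c1 = feature_correlation_matrix(toy_feature_matrix(values)).values
        c2 = feature_correlation_matrix(
            toy_feature_matrix(values[perm], regions=[f"r{i}" for i in perm])
        ).values
        np.testing.assert_allclose(c2, c1[np.ix_(perm, perm)], atol=1e-12)


class TestAbsolute:
    def test_negative_becomes_positive(self):
        c = ConnectivityMatrix(
            values=np.array([[1.0, -0.9], [-0.9, 1.0]]), regions=("a", "b")
        )
        assert absolute_matrix(c).values[0, 1] == pytest.approx(0.9)

    def test_double_absolute_rejected(self):
        c = abs_matrix_from(np.eye(2))
        with pytest.raises(ValueError, match="already"):
            absolute_matrix(c)

    def test_result_nonnegative(self, subject_matrix):
        c = feature_correlation_matrix(zscore_features(subject_matrix))
        assert absolute_matrix(c).values.min() >= 0


class TestBinarize:
    def test_toy_top_two_edges(self):
        # |r| upper triangle in pair order (0,1)=.9 (0,2)=.8 (0,3)=.7 ...
        v = np.eye(4)
        vals = iter([0.9, 0.8, 0.7, 0.6, 0.5, 0.4])
        for i in range(4):
            for j in range(i + 1, 4):
                v[i, j] = v[j, i] = next(vals)
        net = binarize_at_sparsity(abs_matrix_from(v), s=2 / 6)
        expected = np.zeros((4, 4))
        expected[0, 1] = expected[1, 0] = 1
        expected[0, 2] = expected[2, 0] = 1
        np.testing.assert_array_equal(net.adjacency, expected)

    def test_full_sparsity_complete_graph(self):
        rng = np.random.default_rng(1)
        a = np.abs(rng.normal(size=(10, 10)))
        sym = (a + a.T) / 2
        np.fill_diagonal(sym, 1.0)
        net = binarize_at_sparsity(abs_matrix_from(sym), s=1.0)
        assert net.edge_count == 45
        assert check_no_isolated_nodes(net) == []

    def test_edge_count_at_23_percent_of_68_nodes(self):
        rng = np.random.default_rng(2)
        a = np.abs(rng.normal(size=(68, 68)))
        sym = (a + a.T) / 2
        net = binarize_at_sparsity(abs_matrix_from(sym), s=0.23)
        assert net.edge_count == 524  # round(0.23 * 2278)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        a = np.abs(rng.normal(size=(12, 12)))
        sym = (a + a.T) / 2
        n1 = binarize_at_sparsity(abs_matrix_from(sym), 0.3)
        n2 = binarize_at_sparsity(abs_matrix_from(sym * 17.5), 0.3)
        np.testing.assert_array_equal(n1.adjacency, n2.adjacency)

    def test_requires_absolute_matrix(self):
        c = ConnectivityMatrix(values=np.eye(3), regions=("a", "b", "c"))
        with pytest.raises(ValueError, match="absolute"):
            binarize_at_sparsity(c, 0.5)

    def test_zero_edges_rejected(self):
        c = abs_matrix_from(np.eye(3))
        with pytest.raises(ValueError, match="zero edges"):
            binarize_at_sparsity(c, 1e-6)

    def test_tie_break_is_lexicographic(self):
        v = np.full((4, 4), 0.5)
        np.fill_diagonal(v, 1.0)
        net = binarize_at_sparsity(abs_matrix_from(v), s=2 / 6)
        # all |r| tie at 0.5 -> pairs (0,1) and (0,2) chosen
        assert net.adjacency[0, 1] == 1 and net.adjacency[0, 2] == 1
        assert net.edge_count == 2


class TestSweep:
    def test_default_grid_21_networks_with_exact_counts(self, subject_matrix):
        from morphconn.pipeline import build_connectivity

        nets = sparsity_sweep(build_connectivity(subject_matrix), warn_isolated=False)
        assert len(nets) == 21
        expected = [round_half_up(s * 2278) for s in sparsity_grid()]
        assert [n.edge_count for n in nets] == expected
        assert expected[0] == 456 and expected[-1] == 911

    @pytest.mark.parametrize("seed", range(10))
    def test_nestedness(self, seed):
        rng = np.random.default_rng(seed)
        a = np.abs(rng.normal(size=(20, 20)))
        sym = (a + a.T) / 2
        nets = sparsity_sweep(abs_matrix_from(sym), 0.1, 0.5, 0.1, warn_isolated=False)
        for lo, hi in zip(nets, nets[1:]):
            assert np.all(lo.adjacency <= hi.adjacency)

    def test_step_exceeding_range_gives_single_network(self):
        rng = np.random.default_rng(0)
        a = np.abs(rng.normal(size=(10, 10)))
        nets = sparsity_sweep(abs_matrix_from((a + a.T) / 2), 0.3, 0.35, 0.2,
                              warn_isolated=False)
        assert len(nets) == 1 and nets[0].sparsity == 0.3

    def test_isolated_node_warning_and_report(self):
        # node 5 uncorrelated with everyone -> isolated at low sparsity
        v = np.random.default_rng(4).uniform(0.5, 1.0, (6, 6))
        v = (v + v.T) / 2
        v[5, :] = v[:, 5] = 0.0
        np.fill_diagonal(v, 1.0)
        net = binarize_at_sparsity(abs_matrix_from(v), s=0.4)
        assert check_no_isolated_nodes(net) == ["r5"]
        with pytest.warns(UserWarning, match="isolated"):
            sparsity_sweep(abs_matrix_from(v), 0.4, 0.5, 0.1)


class TestBinaryNetworkInvariants:
    def test_self_loops_rejected(self):
        adj = np.eye(3, dtype=np.uint8)
        with pytest.raises(ValueError, match="self-loops"):
            BinaryNetwork(adjacency=adj, sparsity=0.1, regions=("a", "b", "c"))

    def test_asymmetric_rejected(self):
        adj = np.zeros((3, 3), dtype=np.uint8)
        adj[0, 1] = 1
        with pytest.raises(ValueError, match="symmetric"):
            BinaryNetwork(adjacency=adj, sparsity=0.1, regions=("a", "b", "c"))
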