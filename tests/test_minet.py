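"""Plug-in mutual-information estimation and network thresholding.

The estimator is checked entry-wise against an exhaustive joint-table oracle
(independent nested-loop implementation) and cross-checked against
scikit-learn's contingency-based MI.
"""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import mutual_info_score

from methylnet.minet import (
    MIMatrix,
    average_mi,
    build_mi_matrix,
    default_n_bins,
    discretize,
    estimate_mi,
    read_edge_list,
    read_sif,
    threshold_network,
    write_edge_list,
    write_sif,
)
from methylnet.synthetic import MethylationMatrix


def mi_oracle(x, y):
    """Exhaustive plug-in MI from the joint table, scalar loops only."""
    n = len(x)
    pairs = list(zip(x, y))
    mi = 0.0
    for a in set(x):
        for b in set(y):
            pxy = pairs.count((a, b)) / n
            if pxy == 0:
                continue
            px = list(x).count(a) / n
            py = list(y).count(b) / n
            mi += pxy * math.log(pxy / (px * py))
    return mi


def entropy_oracle(x):
    n = len(x)
    return -sum(
        (list(x).count(a) / n) * math.log(list(x).count(a) / n) for a in set(x)
    )


def _as_matrix(arr, prefix="g"):
    arr = np.asarray(arr, dtype=float)
    cols = [f"s{j}" for j in range(arr.shape[1])]
    groups = pd.Series(["case"] * len(cols), index=cols)
    values = pd.DataFrame(arr, index=[f"{prefix}{i}" for i in range(arr.shape[0])], columns=cols)
    return MethylationMatrix(values, groups)


class TestDiscretize:
    def test_edge_value_falls_in_lower_bin(self):
        np.testing.assert_array_equal(discretize([0, 0.5, 1], 2), [0, 0, 1])

    def test_constant_profile_single_bin(self):
        assert set(discretize([0.4] * 6, 3)) == {0}

    def test_single_bin_rejected(self):
        with pytest.raises(ValueError):
            discretize([0.1, 0.2], 1)

    def test_labels_within_range(self, rng):
        labels = discretize(rng.random(100), 5)
        assert labels.min() >= 0 and labels.max() <= 4

    def test_default_bins_sqrt_rule(self):
        assert default_n_bins(12) == 4
        assert default_n_bins(2) == 2


class TestEstimateMI:
    def test_self_information_is_entropy(self):
        x = np.array([0, 0, 1, 1])
        assert estimate_mi(x, x) == pytest.approx(math.log(2), abs=1e-12)

    def test_factorizing_joint_gives_zero(self):
        assert estimate_mi([0, 0, 1, 1], [0, 1, 0, 1]) == 0.0

    def test_constant_marginal_gives_zero(self):
        assert estimate_mi([0, 1, 2, 0], [5, 5, 5, 5]) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            estimate_mi([0, 1], [0, 1, 2])

    def test_matches_exhaustive_oracle_small(self, rng):
        for _ in range(200):
            n = rng.integers(2, 7)
            x = rng.integers(0, 3, n)
            y = rng.integers(0, 3, n)
            assert estimate_mi(x, y) == pytest.approx(
                max(mi_oracle(x, y), 0.0), abs=1e-12
            )

    def test_matches_sklearn(self, rng):
        for _ in range(50):
            x = rng.integers(0, 4, 30)
            y = rng.integers(0, 4, 30)
            assert estimate_mi(x, y) == pytest.approx(
                max(mutual_info_score(x, y), 0.0), abs=1e-10
            )

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(st.integers(0, 3), min_size=2, max_size=12),
        st.data(),
    )
    def test_symmetry_nonnegativity_entropy_bound(self, x, data):
        y = data.draw(st.lists(st.integers(0, 3), min_size=len(x), max_size=len(x)))
        mi = estimate_mi(x, y)
        assert mi == pytest.approx(estimate_mi(y, x), abs=1e-12)
        assert mi >= 0
        assert mi <= min(entropy_oracle(x), entropy_oracle(y)) + 1e-12

    def test_invariant_under_label_permutation(self, rng):
        x = rng.integers(0, 3, 20)
        y = rng.integers(0, 3, 20)
        perm = {0: 2, 1: 0, 2: 1}
        x2 = np.array([perm[v] for v in x])
        assert estimate_mi(x, y) == pytest.approx(estimate_mi(x2, y), abs=1e-12)


class TestMIMatrix:
    def test_identical_profiles_give_marginal_entropy(self):
        row = [0.1, 0.2, 0.8, 0.9]
        m = build_mi_matrix(_as_matrix([row, row]), n_bins=2)
        assert m.values[0, 1] == pytest.approx(math.log(2), abs=1e-12)

    def test_symmetric_with_zero_diagonal(self, rng):
        m = build_mi_matrix(_as_matrix(rng.random((6, 10))), n_bins=3)
        np.testing.assert_allclose(m.values, m.values.T)
        np.testing.assert_array_equal(np.diag(m.values), 0.0)

    def test_matches_nested_loop_oracle(self, rng):
        arr = rng.random((5, 8))
        m = build_mi_matrix(_as_matrix(arr), n_bins=3)
        for i in range(5):
            for j in range(5):
                if i == j:
                    continue
                expected = mi_oracle(
                    list(discretize(arr[i], 3)), list(discretize(arr[j], 3))
                )
                assert m.values[i, j] == pytest.approx(max(expected, 0.0), abs=1e-12)

    def test_degenerate_dimensions_rejected(self, rng):
        with pytest.raises(ValueError):
            build_mi_matrix(_as_matrix(rng.random((1, 10))))
        with pytest.raises(ValueError):
            build_mi_matrix(_as_matrix(rng.random((4, 2))))


class TestThresholdNetwork:
    def _mi(self, values, nodes=None):
        n = len(values)
        nodes = nodes or [f"n{i}" for i in range(n)]
        return MIMatrix(nodes, np.asarray(values, dtype=float), "test")

    def test_all_zero_matrix_gives_isolated_nodes(self):
        net = threshold_network(self._mi(np.zeros((4, 4))))
        assert net.number_of_nodes() == 4
        assert net.number_of_edges() == 0

    def test_edge_count_matches_entries_above_threshold(self, rng):
        vals = np.zeros((42, 42))
        iu = np.triu_indices(42, k=1)
        pick = rng.choice(len(iu[0]), size=316, replace=False)
        vals[iu[0][pick], iu[1][pick]] = rng.uniform(0.1, 1.0, 316)
        vals = vals + vals.T
        net = threshold_network(self._mi(vals))
        assert net.number_of_edges() == 316

    def test_infinite_threshold_empties_edges(self, rng):
        vals = rng.random((5, 5))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0)
        net = threshold_network(self._mi(vals), tau=np.inf)
        assert net.number_of_edges() == 0

    def test_tolerance_suppresses_phantom_edges(self):
        vals = np.array([[0.0, 1e-15], [1e-15, 0.0]])
        net = threshold_network(self._mi(vals))
        assert net.number_of_edges() == 0


class TestAverageMI:
    def test_single_edge(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.42)
        assert average_mi(g) == pytest.approx(0.42)

    def test_two_edges_mean(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.1)
        g.add_edge("b", "c", weight=0.3)
        assert average_mi(g) == pytest.approx(0.2)

    def test_empty_edge_set_rejected(self):
        g = nx.Graph()
        g.add_nodes_from("ab")
        with pytest.raises(ValueError):
            average_mi(g)

    def test_comethylated_class_has_larger_average_mi(self, rng):
        # shared latent factor drives co-methylation in one class; the other
        # is independent noise
        n_genes, n_samples = 20, 12
        latent = rng.normal(0, 1, n_samples)
        correlated = 1 / (1 + np.exp(-(latent + 0.3 * rng.normal(0, 1, (n_genes, n_samples)))))
        independent = rng.random((n_genes, n_samples))
        net_c = threshold_network(build_mi_matrix(_as_matrix(correlated, "c")))
        net_i = threshold_network(build_mi_matrix(_as_matrix(independent, "i")))
        assert average_mi(net_c) > average_mi(net_i)


class TestInterchange:
    def test_edge_list_round_trip(self, rng, tmp_path):
        vals = rng.random((6, 6))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0)
        net = threshold_network(MIMatrix([f"n{i}" for i in range(6)], vals, "t"))
        path = tmp_path / "edges.tsv"
        write_edge_list(net, path)
        back = read_edge_list(path, nodes=net.nodes())
        assert set(back.edges()) == set(net.edges())
        for u, v, d in net.edges(data=True):
            assert back[u][v]["weight"] == pytest.approx(d["weight"], rel=1e-9)

    def test_sif_round_trip_preserves_isolated_nodes(self, tmp_path):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.5)
        g.add_node("lonely")
        path = tmp_path / "net.sif"
        write_sif(g, path)
        back = read_sif(path)
        assert set(back.nodes()) == {"a", "b", "lonely"}
        assert set(back.edges()) == {("a", "b")}
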