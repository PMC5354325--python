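"""Participation coefficients and connector classification."""

import numpy as np
import pytest

from topoact.communities import UNASSIGNED
from topoact.errors import ParameterError
from topoact.graph import ZMatrix, threshold_density
from topoact.topology import (
    ROLE_CONNECTOR,
    ROLE_EXCLUDED,
    ROLE_NON_CONNECTOR,
    classify_connectors,
    participation_coefficient,
    summed_pc,
)

from conftest import (
    graph_from_adjacency,
    naive_participation_coefficient,
    partition_from_labels,
)


def _star_graph(weights_by_system):
    """Node 0 connected to one node of each listed system with given weight."""
    n = 1 + len(weights_by_system)
    adj = np.zeros((n, n))
    labels = ["s0"]
    for k, (system, w) in enumerate(weights_by_system, start=1):
        adj[0, k] = adj[k, 0] = w
        labels.append(system)
    return graph_from_adjacency(adj), partition_from_labels(np.array(labels))


class TestParticipationCoefficient:
    def test_fully_within_system_node_scores_zero(self):
        g, part = _star_graph([("s0", 1.0), ("s0", 2.0)])
        assert participation_coefficient(g, part)[0] == pytest.approx(0.0)

    def test_equal_four_way_split_scores_three_quarters(self):
        g, part = _star_graph([("s0", 1.0), ("s1", 1.0), ("s2", 1.0), ("s3", 1.0)])
        assert participation_coefficient(g, part)[0] == pytest.approx(0.75)

    def test_two_one_one_weight_split(self):
        # weights {own: 2, B: 1, C: 1} -> 1 - (0.5^2 + 0.25^2 + 0.25^2) = 0.625
        g, part = _star_graph([("s0", 2.0), ("s1", 1.0), ("s2", 1.0)])
        assert participation_coefficient(g, part)[0] == pytest.approx(0.625)

    def test_literal_variant_excludes_own_system(self):
        g, part = _star_graph([("s0", 1.0), ("s0", 2.0)])
        assert participation_coefficient(g, part, variant="literal")[0] == pytest.approx(1.0)
        with pytest.raises(ParameterError):
            participation_coefficient(g, part, variant="nope")

    def test_matches_double_loop_oracle_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(5, 31))
            adj = np.triu(rng.uniform(0, 1, (n, n)) * (rng.random((n, n)) < 0.4), 1)
            adj = adj + adj.T
            n_sys = int(rng.integers(2, 7))
            labels = np.array([f"s{k}" for k in rng.integers(0, n_sys, n)], dtype=object)
            g = graph_from_adjacency(adj)
            part = partition_from_labels(labels)
            for variant in ("standard", "literal"):
                got = participation_coefficient(g, part, variant=variant)
                want = naive_participation_coefficient(adj, labels, variant=variant)
                assert np.abs(got - want).max() <= 1e-12

    def test_range_bounded_by_system_count(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = 20
            adj = np.abs(rng.normal(size=(n, n)))
            adj = (adj + adj.T) / 2
            np.fill_diagonal(adj, 0.0)
            n_sys = int(rng.integers(2, 6))
            labels = np.array([f"s{k}" for k in rng.integers(0, n_sys, n)], dtype=object)
            pc = participation_coefficient(
                graph_from_adjacency(adj), partition_from_labels(labels)
            )
            present = len(set(labels))
            assert np.all(pc >= -1e-12)
            assert np.all(pc <= 1 - 1 / present + 1e-12)

    def test_isolated_node_gets_zero_with_warning(self):
        adj = np.zeros((3, 3))
        adj[0, 1] = adj[1, 0] = 1.0
        g = graph_from_adjacency(adj)
        part = partition_from_labels(np.array(["a", "a", "a"], dtype=object))
        with pytest.warns(UserWarning, match="no retained weight"):
            pc = participation_coefficient(g, part)
        assert pc[2] == 0.0

    def test_edges_to_unassigned_nodes_dropped(self):
        g, part = _star_graph([("s1", 1.0), (UNASSIGNED, 5.0)])
        # only the s1 edge counts: all retained weight in one other system
        pc = participation_coefficient(g, part)
        assert pc[0] == pytest.approx(1.0 - 1.0)


class TestSummedPC:
    @staticmethod
    def _setup(seed=0, n=24):
        rng = np.random.default_rng(seed)
        z = np.abs(rng.normal(size=(n, n)))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0.0)
        zm = ZMatrix(node_ids=[f"n{i:03d}" for i in range(n)], z=z)
        labels = np.array([f"s{k}" for k in rng.integers(0, 3, n)], dtype=object)
        part = partition_from_labels(labels)

        class FakeConsensus:
            partitions = {}

            def partition_at(self, d):
                return part

        cons = FakeConsensus()
        cons.partitions = {d: part for d in (0.05, 0.1, 0.2)}
        return zm, cons, labels

    def test_single_density_sum_equals_that_density(self):
        zm, cons, labels = self._setup()
        table = summed_pc(zm, cons, densities=(0.1,))
        np.testing.assert_allclose(table["pc_sum"], table["pc_d10"])

    def test_sum_matches_per_density_oracle(self):
        zm, cons, labels = self._setup()
        densities = (0.05, 0.1, 0.2)
        table = summed_pc(zm, cons, densities=densities)
        expected = np.zeros(zm.n_nodes)
        for d in densities:
            g = threshold_density(zm, d)
            expected += naive_participation_coefficient(g.adjacency, labels)
        np.testing.assert_allclose(table["pc_sum"], expected, atol=1e-10)

    def test_zero_pc_everywhere_sums_to_zero(self):
        n = 8
        z = np.zeros((n, n))
        # one within-system block only: every node fully within its system
        z[:4, :4] = 0.5
        np.fill_diagonal(z, 0.0)
        zm = ZMatrix(node_ids=[f"n{i:03d}" for i in range(n)], z=z)
        labels = np.array(["a"] * 4 + ["b"] * 4, dtype=object)

        class C:
            def partition_at(self, d):
                return partition_from_labels(labels)

        c = C()
        c.partitions = {0.5: None}
        table = summed_pc(zm, c, densities=(0.5,))
        np.testing.assert_allclose(table["pc_sum"], 0.0)


class TestClassifyConnectors:
    def test_median_rule_with_tie_at_median(self):
        part = partition_from_labels(np.array(["s"] * 3, dtype=object))
        roles = classify_connectors(np.array([0.2, 0.4, 0.6]), part)
        assert list(roles) == [ROLE_NON_CONNECTOR, ROLE_NON_CONNECTOR, ROLE_CONNECTOR]

    def test_two_distinct_nodes_split_evenly(self):
        part = partition_from_labels(np.array(["s", "s"], dtype=object))
        roles = classify_connectors(np.array([0.1, 0.9]), part)
        assert sorted(roles) == [ROLE_CONNECTOR, ROLE_NON_CONNECTOR]

    def test_all_equal_pc_means_no_connectors(self):
        part = partition_from_labels(np.array(["s"] * 5, dtype=object))
        roles = classify_connectors(np.full(5, 0.3), part)
        assert set(roles) == {ROLE_NON_CONNECTOR}

    def test_unassigned_nodes_excluded(self):
        labels = np.array(["s", "s", UNASSIGNED], dtype=object)
        part = partition_from_labels(labels)
        roles = classify_connectors(np.array([0.1, 0.9, 0.5]), part)
        assert roles[2] == ROLE_EXCLUDED

    def test_connectors_never_outnumber_non_connectors(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(2, 15))
            labels = np.array(["s"] * n, dtype=object)
            roles = classify_connectors(rng.uniform(size=n),
                                        partition_from_labels(labels))
            assert (roles == ROLE_CONNECTOR).sum() <= (roles == ROLE_NON_CONNECTOR).sum()

    def test_tiny_system_rejected(self):
        part = partition_from_labels(np.array(["s", "t", "t"], dtype=object))
        with pytest.raises(ParameterError, match="'s'"):
            classify_connectors(np.array([0.1, 0.2, 0.3]), part)
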