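"""Dynamic thresholding, edge construction, and community detection."""

import numpy as np
import pytest

from nlnet import (Partition, build_network, communities_label_propagation,
                   communities_multilevel, pair_support, select_cutoff)
from nlnet.inference import LfdrMatrix


def lfdr_from(arr):
    arr = np.asarray(arr, dtype=float)
    np.fill_diagonal(arr, 1.0)
    return LfdrMatrix(arr)


def symmetric_lfdr(rng, p, low=0.0, high=1.0):
    a = rng.uniform(low, high, (p, p))
    a = np.minimum(a, a.T)
    np.fill_diagonal(a, 1.0)
    return LfdrMatrix(a)


def two_cliques_with_bridge():
    """Two 10-cliques joined by a single bridge edge, encoded as lfdr."""
    p = 20
    l = np.ones((p, p))
    for block in (range(10), range(10, 20)):
        for i in block:
            for j in block:
                if i != j:
                    l[i, j] = 0.01
    l[9, 10] = l[10, 9] = 0.01
    return build_network(lfdr_from(l), cutoff=0.05)


class TestSelectCutoff:
    def test_clamped_to_ceiling(self, rng):
        l = symmetric_lfdr(rng, 30, low=0.4, high=1.0)  # c* ~ 0.5
        assert select_cutoff(l, target_degree=10) == 0.2

    def test_clamped_to_floor(self, rng):
        l = symmetric_lfdr(rng, 30, low=0.0, high=0.02)  # c* ~ 0.01
        assert select_cutoff(l, target_degree=10) == 0.05

    def test_inside_band_passes_through(self):
        p = 10
        l = np.full((p, p), 0.9)
        ii, jj = np.triu_indices(p, 1)
        # plant exactly 15 pairwise values at 0.12 -> c* for 15 edges is 0.12
        l[ii[:15], jj[:15]] = l[jj[:15], ii[:15]] = 0.12
        c = select_cutoff(lfdr_from(l), target_degree=3.0)  # 3*10/2 = 15 edges
        assert c == pytest.approx(0.12)

    def test_realized_degree_near_target_when_unclamped(self, rng):
        """At the unclamped order-statistic cutoff the realized average
        degree lands within 1 of the request (ties aside)."""
        for seed in range(3):
            r = np.random.default_rng(seed)
            l = symmetric_lfdr(r, 60)
            target = 10.0
            p = 60
            support = pair_support(l)
            vals = np.sort(support[np.triu_indices(p, 1)])
            c_star = vals[int(round(target * p / 2)) - 1]
            net = build_network(l, min(max(c_star, 1e-9), 1.0))
            assert abs(net.average_degree() - target) <= 1.0

    def test_bad_target_rejected(self, rng):
        with pytest.raises(ValueError):
            select_cutoff(symmetric_lfdr(rng, 10), target_degree=20)


class TestBuildNetwork:
    def test_union_rule_one_direction_suffices(self):
        l = np.ones((3, 3))
        l[0, 1] = 0.01   # significant in one direction only
        l[1, 0] = 0.9
        net = build_network(lfdr_from(l), cutoff=0.05)
        assert net.graph.has_edge("0", "1")
        assert net.graph.number_of_edges() == 1
        inter = build_network(lfdr_from(l.copy()), 0.05, symmetrization="intersection")
        assert inter.graph.number_of_edges() == 0

    def test_all_ones_gives_edgeless_graph(self):
        net = build_network(lfdr_from(np.ones((5, 5))), cutoff=0.2)
        assert net.graph.number_of_edges() == 0
        assert net.graph.number_of_nodes() == 5

    def test_counting_oracle_on_hand_matrix(self):
        l = np.ones((5, 5))
        pairs = [(0, 1, 0.01), (0, 2, 0.04), (1, 3, 0.05), (2, 4, 0.30)]
        for i, j, v in pairs:
            l[i, j] = l[j, i] = v
        net = build_network(lfdr_from(l), cutoff=0.05)
        assert net.graph.number_of_edges() == 3  # the three values <= 0.05

    def test_transpose_invariance(self, rng):
        a = rng.uniform(size=(12, 12))
        np.fill_diagonal(a, 1.0)
        e1 = build_network(LfdrMatrix(a), 0.2).edge_table()
        e2 = build_network(LfdrMatrix(a.T.copy()), 0.2).edge_table()
        assert e1 == e2

    def test_average_degree_monotone_in_cutoff(self, rng):
        l = symmetric_lfdr(rng, 25)
        degs = [build_network(l, c).average_degree()
                for c in (0.05, 0.1, 0.2, 0.5, 1.0)]
        assert degs == sorted(degs)


class TestCommunities:
    def test_multilevel_splits_bridged_cliques(self):
        net = two_cliques_with_bridge()
        part = communities_multilevel(net, seed=3, min_size=5)
        arr = part.as_array([str(i) for i in range(20)])
        assert len(set(arr[:10])) == 1 and len(set(arr[10:])) == 1
        assert arr[0] != arr[10]

    def test_single_clique_is_one_community(self):
        l = np.full((8, 8), 0.01)
        net = build_network(lfdr_from(l), 0.05)
        part = communities_multilevel(net, seed=0, min_size=2)
        assert set(part.labels.values()) == {1}

    def test_edgeless_graph_all_unassigned(self):
        net = build_network(lfdr_from(np.ones((6, 6))), 0.1)
        for detect in (communities_multilevel, communities_label_propagation):
            part = detect(net, seed=0, min_size=3)
            assert set(part.labels.values()) == {0}

    def test_label_propagation_majority_splits_cliques(self):
        net = two_cliques_with_bridge()
        hits = 0
        for seed in range(10):
            arr = communities_label_propagation(net, seed=seed, min_size=5)\
                .as_array([str(i) for i in range(20)])
            if (len(set(arr[:10])) == 1 and len(set(arr[10:])) == 1
                    and arr[0] != arr[10]):
                hits += 1
        assert hits > 5

    def test_methods_agree_on_planted_modules(self, rng):
        """Both algorithms recover strong planted structure (ARI >= 0.8)."""
        from nlnet import adjusted_rand_index
        p_per, k = 20, 5
        p = p_per * k
        l = np.ones((p, p))
        for m in range(k):
            sl = slice(m * p_per, (m + 1) * p_per)
            l[sl, sl] = rng.uniform(0.0, 0.04, (p_per, p_per))
        net = build_network(lfdr_from(l), 0.05)
        ids = [str(i) for i in range(p)]
        a = communities_multilevel(net, seed=1, min_size=5).as_array(ids)
        b = communities_label_propagation(net, seed=1, min_size=5).as_array(ids)
        assert adjusted_rand_index(a, b) >= 0.8

    def test_determinism_under_seed(self):
        net = two_cliques_with_bridge()
        a = communities_multilevel(net, seed=11, min_size=2).labels
        b = communities_multilevel(net, seed=11, min_size=2).labels
        assert a == b

    def test_partition_covers_all_nodes(self):
        net = two_cliques_with_bridge()
        part = communities_multilevel(net, seed=0, min_size=2)
        assert set(part.labels) == set(net.graph.nodes)

    def test_partition_min_size_invariant(self):
        with pytest.raises(ValueError):
            Partition(labels={"a": 1, "b": 2, "c": 2}, min_size=2)
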