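"""Community detection: modularity closed forms and brute-force checks,
Louvain recovery against exhaustive search, consensus-partition
behaviour, NMI conventions and sub-network labeling."""

import warnings

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from betaconn.community import (
    Partition,
    agreement_matrix,
    consensus_partition,
    group_representative,
    label_subnetworks,
    louvain,
    louvain_ensemble,
    modularity_q,
    nmi,
)
from betaconn.construction import BinaryNetwork, proportional_threshold, WeightedNetwork
from betaconn.synthetic import GroundTruth, build_block_correlation

from conftest import complete, network
from oracles import best_partition_exhaustive, bf_modularity, random_connected_graph


class TestModularity:
    def test_two_disconnected_cliques(self, two_cliques):
        part = np.array([0, 0, 0, 1, 1, 1])
        assert modularity_q(two_cliques, part) == pytest.approx(0.5)

    def test_single_community_is_zero(self, two_cliques):
        assert modularity_q(two_cliques, np.zeros(6, dtype=int)) == pytest.approx(0.0)

    def test_any_partition_of_complete_graph_not_positive(self):
        k4 = complete(4)
        # all partitions of 4 nodes, by brute force
        _, best_q = best_partition_exhaustive(k4.a.astype(float))
        assert best_q <= 1e-12

    def test_matches_brute_force_and_networkx(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            n = int(rng.integers(4, 8))
            a = random_connected_graph(n, rng)
            part = rng.integers(0, 3, size=n)
            bn = BinaryNetwork(a=a, density=float("nan"))
            q = modularity_q(bn, part)
            assert q == pytest.approx(bf_modularity(a.astype(float), part))
            communities = [
                set(np.flatnonzero(part == c)) for c in np.unique(part)
            ]
            q_nx = nx.community.modularity(nx.from_numpy_array(a), communities)
            assert q == pytest.approx(q_nx)

    def test_edgeless_network_fails(self):
        with pytest.raises(ValueError):
            modularity_q(network(3, []), np.zeros(3, dtype=int))


class TestLouvain:
    def test_recovers_two_cliques_optimum(self, two_cliques):
        exp_assign, exp_q = best_partition_exhaustive(two_cliques.a.astype(float))
        p = louvain(two_cliques, seed=0)
        assert p.q == pytest.approx(exp_q) == pytest.approx(0.5)
        assert nmi(p.assignment, exp_assign) == pytest.approx(1.0)

    def test_complete_graph_single_community(self):
        p = louvain(complete(6), seed=1)
        assert p.n_communities == 1

    def test_reported_q_matches_recomputation(self):
        rng = np.random.default_rng(5)
        for seed in range(5):
            a = random_connected_graph(12, rng)
            bn = BinaryNetwork(a=a, density=float("nan"))
            p = louvain(bn, seed=seed)
            assert p.q == pytest.approx(modularity_q(bn, p.assignment))
            # no worse than the all-singleton start
            assert p.q >= modularity_q(bn, np.arange(12)) - 1e-12

    def test_planted_block_recovery_over_seeds(self):
        """Thresholding the planted block correlation matrix itself and
        running Louvain recovers the 4-module structure."""
        truth = GroundTruth(
            partition=np.repeat(np.arange(4), 15),
            target_node=None,
            role_profile={},
        )
        c = build_block_correlation(truth)
        # small symmetric jitter stands in for sampling noise; without it
        # the all-tied within-module weights interact with the
        # deterministic tie rule and starve the later modules
        rng = np.random.default_rng(8)
        eps = rng.normal(0, 0.02, size=(60, 60))
        w = c - np.eye(60) + (eps + eps.T) / 2
        np.fill_diagonal(w, 0.0)
        bn = proportional_threshold(WeightedNetwork(w=w), 15.0)
        scores = [
            nmi(louvain(bn, seed=s).assignment, truth.partition)
            for s in range(100)
        ]
        assert np.mean(np.asarray(scores) >= 0.9) >= 0.9


class TestConsensus:
    def test_identical_inputs_return_immediately(self):
        p = Partition(assignment=np.array([0, 0, 1, 1]))
        out = consensus_partition([p, p, p], seed=0)
        assert np.array_equal(out.assignment, p.assignment)

    def test_majority_partition_wins(self):
        rng = np.random.default_rng(0)
        x = Partition(assignment=np.repeat([0, 1, 2], 10))
        noise = [
            Partition(assignment=rng.integers(0, 3, size=30))
            for _ in range(10)
        ]
        out = consensus_partition([x] * 90 + noise, tau=0.5, n_iter=30, seed=1)
        assert nmi(out, x) == pytest.approx(1.0)

    def test_empty_agreement_yields_singletons_with_warning(self):
        # three pairwise-crossing partitions: every pair co-assigned in
        # only 1/3 of them, so thresholding at tau = 0.5 empties the
        # agreement matrix
        p2 = Partition(assignment=np.array([0, 0, 1, 1]))
        p3 = Partition(assignment=np.array([0, 1, 0, 1]))
        p4 = Partition(assignment=np.array([0, 1, 1, 0]))
        with pytest.warns(UserWarning, match="singleton"):
            out = consensus_partition([p2, p3, p4], tau=0.5, n_iter=10, seed=0)
        assert out.n_communities == 4

    def test_consensus_is_idempotent(self):
        rng = np.random.default_rng(2)
        parts = [
            Partition(assignment=np.repeat([0, 1, 2], 8)) for _ in range(8)
        ] + [Partition(assignment=rng.integers(0, 3, size=24)) for _ in range(2)]
        out = consensus_partition(parts, tau=0.5, n_iter=20, seed=3)
        again = consensus_partition([out] * 5, tau=0.5, n_iter=20, seed=4)
        assert np.array_equal(out.assignment, again.assignment)

    def test_agreement_matrix_values(self):
        p1 = Partition(assignment=np.array([0, 0, 1]))
        p2 = Partition(assignment=np.array([0, 1, 1]))
        d = agreement_matrix([p1, p2])
        assert d[0, 1] == pytest.approx(0.5)
        assert d[1, 2] == pytest.approx(0.5)
        assert d[0, 2] == pytest.approx(0.0)
        assert np.allclose(np.diag(d), 0.0)


class TestGroupRepresentative:
    def test_shared_partition_is_returned(self):
        p = Partition(assignment=np.repeat([0, 1], 10))
        rep = group_representative([p] * 6, seed=0)
        assert rep.level == "group"
        assert np.array_equal(rep.assignment, p.assignment)

    def test_disjoint_structure_flagged_degenerate(self):
        # pairwise-crossing participant partitions share no reliable
        # co-assignment: the representative degenerates to singletons
        parts = [
            Partition(assignment=np.array([0, 0, 1, 1])),
            Partition(assignment=np.array([0, 1, 0, 1])),
            Partition(assignment=np.array([0, 1, 1, 0])),
        ]
        with pytest.warns(UserWarning):
            rep = group_representative(parts, seed=0)
        assert rep.degenerate


class TestNmi:
    def test_relabeling_invariance(self):
        p = np.array([0, 0, 1, 1, 2, 2])
        relabeled = np.array([2, 2, 0, 0, 1, 1])
        assert nmi(p, relabeled) == pytest.approx(1.0)

    def test_single_community_convention(self):
        p = np.array([0, 0, 1, 1])
        trivial = np.zeros(4, dtype=int)
        assert nmi(p, trivial) == 0.0
        assert nmi(trivial, trivial) == 1.0

    def test_crossed_pairs_have_zero_information(self):
        assert nmi(np.array([0, 0, 1, 1]), np.array([0, 1, 0, 1])) == pytest.approx(0.0)

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            a = rng.integers(0, 4, size=20)
            b = rng.integers(0, 4, size=20)
            assert nmi(a, b) == pytest.approx(nmi(b, a))

    def test_mismatched_node_sets_rejected(self):
        with pytest.raises(ValueError):
            nmi(np.zeros(3, dtype=int), np.zeros(4, dtype=int))


class TestLabelSubnetworks:
    def test_identity_partition_maps_one_to_one(self):
        part = Partition(assignment=np.repeat([0, 1, 2], 5))
        ref = pd.Series(
            np.repeat(["VN", "FPN", "DMN"], 5), index=range(15)
        )
        mapping, table = label_subnetworks(part, ref)
        assert mapping == {0: "VN", 1: "FPN", 2: "DMN"}
        best = table.loc[table.groupby("community")["jaccard"].idxmax()]
        assert np.allclose(best["jaccard"], 1.0)

    def test_straddling_community_labeled_by_majority(self):
        # one community overlapping two reference networks 60/40
        part = Partition(assignment=np.zeros(10, dtype=int))
        ref = pd.Series(["A"] * 6 + ["B"] * 4, index=range(10))
        mapping, table = label_subnetworks(part, ref)
        assert mapping[0] == "A"
        overlaps = table.set_index("reference")["overlap"]
        assert overlaps["A"] == 6 and overlaps["B"] == 4

    def test_no_overlap_is_unassigned(self):
        part = Partition(assignment=np.array([0, 0, 1, 1]))
        # reference covers only nodes of community 0
        ref = pd.Series(["A", "A", "A", "A"], index=[0, 1, 4, 5])
        with pytest.raises(ValueError):
            label_subnetworks(part, ref)  # < 80% coverage
        ref_ok = pd.Series(["A"] * 2, index=[0, 1]).reindex(range(4))
        # fully covered but empty label set for community 1
        ref_ok = pd.Series(["A", "A", "B", "B"], index=range(4))
        mapping, _ = label_subnetworks(part, ref_ok)
        assert mapping == {0: "A", 1: "B"}

    def test_tie_broken_by_overlap_then_label(self):
        part = Partition(assignment=np.zeros(4, dtype=int))
        ref = pd.Series(["B", "B", "A", "A"], index=range(4))
        mapping, _ = label_subnetworks(part, ref)
        # equal jaccard and overlap -> lexicographically smaller label
        assert mapping[0] == "A"

    def test_target_community_flagged(self):
        part = Partition(assignment=np.array([0, 0, 1, 1]))
        ref = pd.Series(["A", "A", "B", "B"], index=range(4))
        _, table = label_subnetworks(part, ref, target_node=3)
        assert set(table[table["contains_target"]]["community"]) == {1}


def test_louvain_ensemble_is_seed_deterministic(two_cliques):
    e1 = louvain_ensemble(two_cliques, n_runs=5, seed=3)
    e2 = louvain_ensemble(two_cliques, n_runs=5, seed=3)
    for a, b in zip(e1, e2):
        assert np.array_equal(a.assignment, b.assignment)
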