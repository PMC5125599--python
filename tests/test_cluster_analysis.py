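import itertools

import numpy as np
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from metapopnet.cluster_analysis import (
    Dendrogram,
    analyze_clusters,
    average_linkage_dendrogram,
    cophenetic_correlation,
    max_modularity_partition,
    modularity,
    out_in_ratios,
    symmetrize_excluding_self,
)
from metapopnet.network_builder import DispersalNetwork
from metapopnet.synthetic_data import planted_partition_matrix


def random_similarity(rng, n):
    """Symmetric non-negative matrix with distinct off-diagonal entries."""
    vals = rng.permutation(np.arange(1, n * (n - 1) // 2 + 1)).astype(float)
    vals += rng.uniform(0, 0.5, size=vals.size)
    S = np.zeros((n, n))
    S[np.triu_indices(n, 1)] = vals
    return S + S.T


def brute_force_cophenetic(dendrogram):
    """Independent cophenetic matrix: for each leaf pair, walk the merge list."""
    n = len(dendrogram.leaves)
    members = [{i} for i in range(n)]
    C = np.zeros((n, n))
    for a, b, h in dendrogram.merges:
        for i in members[a]:
            for j in members[b]:
                C[i, j] = C[j, i] = h
        members.append(members[a] | members[b])
    return C


def paper_like_network():
    """Total network mirroring the published cluster structure (order W,S,C,NE,NW)."""
    names = ("W", "S", "C", "NE", "NW")
    W = np.zeros((5, 5), dtype=int)
    ix = {n: i for i, n in enumerate(names)}
    for a, b, v in [
        ("NE", "C", 78), ("C", "NE", 13), ("NW", "W", 52), ("W", "NW", 20),
        ("NE", "S", 17), ("NE", "W", 9), ("NE", "NW", 8),
        ("C", "W", 4), ("C", "S", 4), ("C", "NW", 4),
        ("NW", "S", 3), ("NW", "C", 3), ("NW", "NE", 2),
        ("W", "S", 5), ("W", "C", 5), ("W", "NE", 4),
        ("S", "NE", 2), ("S", "C", 3), ("S", "W", 2), ("S", "NW", 1),
    ]:
        W[ix[a], ix[b]] = v
    return DispersalNetwork(names, W, np.zeros(5, dtype=int))


class TestSymmetrize:
    def test_directed_counts_sum(self):
        net = paper_like_network()
        S = symmetrize_excluding_self(net)
        i, j = net.index("NE"), net.index("C")
        assert S[i, j] == S[j, i] == 91

    def test_self_counts_never_enter(self):
        net = paper_like_network()
        with_self = DispersalNetwork(net.populations, net.W, np.full(5, 100))
        np.testing.assert_array_equal(
            symmetrize_excluding_self(net), symmetrize_excluding_self(with_self)
        )
        assert np.all(np.diag(symmetrize_excluding_self(with_self)) == 0)


class TestDendrogram:
    def test_two_leaves_single_merge_at_their_similarity(self):
        S = np.array([[0.0, 7.5], [7.5, 0.0]])
        d = average_linkage_dendrogram(S, ["a", "b"])
        assert d.merges == ((0, 1, 7.5),)

    def test_planted_blocks_merge_first(self):
        S = planted_partition_matrix(2, 10.0, 0.0)
        d = average_linkage_dendrogram(S, ["a", "b", "c", "d"])
        first_two = {frozenset(m[:2]) for m in d.merges[:2]}
        assert first_two == {frozenset({0, 1}), frozenset({2, 3})}

    def test_heights_monotone_non_increasing(self, rng):
        for n in (3, 4, 5, 6):
            S = random_similarity(rng, n)
            d = average_linkage_dendrogram(S)
            heights = [h for _, _, h in d.merges]
            assert all(h1 >= h2 - 1e-12 for h1, h2 in zip(heights, heights[1:]))

    def test_matches_scipy_upgma_under_distance_transform(self, rng):
        # UPGMA on similarities == UPGMA on (K - S) distances: the affine map
        # commutes with averaging, so cophenetic heights must satisfy C + C' = K
        for n in (4, 5, 6):
            S = random_similarity(rng, n)
            K = S.max() + 1.0
            D = K - S
            np.fill_diagonal(D, 0.0)
            Z = hierarchy.linkage(squareform(D, checks=True), method="average")
            C_dist = squareform(hierarchy.cophenet(Z))
            C_sim = average_linkage_dendrogram(S).cophenetic_matrix()
            off = ~np.eye(n, dtype=bool)
            np.testing.assert_allclose(C_sim[off] + C_dist[off], K, rtol=1e-10)

    def test_fewer_than_two_leaves_is_an_error(self):
        with pytest.raises(ValueError):
            average_linkage_dendrogram(np.zeros((1, 1)), ["a"])


class TestCopheneticCorrelation:
    def test_ultrametric_matrix_is_reproduced_exactly(self):
        # block matrix is ultrametric: within 10, across 4
        S = planted_partition_matrix(2, 10.0, 4.0)
        d = average_linkage_dendrogram(S)
        np.testing.assert_allclose(d.cophenetic_matrix(), S, atol=1e-12)
        assert cophenetic_correlation(d, S) == pytest.approx(1.0)

    def test_three_leaves_match_direct_pearson(self):
        S = np.array([[0, 5, 2], [5, 0, 1], [2, 1, 0]], dtype=float)
        d = average_linkage_dendrogram(S)
        C = d.cophenetic_matrix()
        iu = np.triu_indices(3, 1)
        expected = np.corrcoef(S[iu], C[iu])[0, 1]
        assert cophenetic_correlation(d, S) == pytest.approx(expected, abs=1e-15)

    def test_agrees_with_brute_force_to_machine_precision(self, rng):
        for n in (3, 4, 5, 6):
            S = random_similarity(rng, n)
            d = average_linkage_dendrogram(S)
            iu = np.triu_indices(n, 1)
            C = brute_force_cophenetic(d)
            expected = np.corrcoef(S[iu], C[iu])[0, 1]
            assert cophenetic_correlation(d, S) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_is_reported_as_undefined(self):
        S = planted_partition_matrix(1, 3.0, 0.0, block_sizes=[3])  # all off-diag equal
        d = average_linkage_dendrogram(S)
        with pytest.warns(UserWarning, match="zero variance"):
            assert cophenetic_correlation(d, S) is None

    def test_strong_planted_blocks_give_high_ccc(self, rng):
        hits = 0
        for _ in range(100):
            S = planted_partition_matrix(2, 10.0, 1.0, [3, 3])
            noise = rng.uniform(0, 1.0, size=S.shape)
            noise = (noise + noise.T) / 2
            np.fill_diagonal(noise, 0.0)
            S = S + noise
            d = average_linkage_dendrogram(S)
            if cophenetic_correlation(d, S) > 0.8:
                hits += 1
        assert hits >= 95


class TestModularity:
    def test_one_cluster_partition_is_exactly_zero(self, rng):
        for n in (3, 5, 6):
            S = random_similarity(rng, n)
            assert modularity(S, [set(range(n))]) == pytest.approx(0.0, abs=1e-15)

    def test_two_disconnected_dyads_reach_half(self):
        S = planted_partition_matrix(2, 10.0, 0.0)
        d = average_linkage_dendrogram(S, ["a", "b", "c", "d"])
        partition, q_max, _ = max_modularity_partition(d, S)
        assert q_max == pytest.approx(0.5)
        assert partition["a"] == partition["b"] != partition["c"]

    def test_uniform_ties_resolve_to_one_cluster(self):
        S = planted_partition_matrix(2, 1.0, 1.0)
        d = average_linkage_dendrogram(S)
        partition, q_max, _ = max_modularity_partition(d, S)
        assert q_max == pytest.approx(0.0, abs=1e-12)
        assert len(set(partition.values())) == 1

    def test_invariance_to_relabeling_and_scaling(self, rng):
        S = random_similarity(rng, 5)
        names = ["a", "b", "c", "d", "e"]
        _, q1, _ = max_modularity_partition(average_linkage_dendrogram(S, names), S)
        perm = rng.permutation(5)
        S2 = S[np.ix_(perm, perm)]
        _, q2, _ = max_modularity_partition(
            average_linkage_dendrogram(S2, [names[i] for i in perm]), S2
        )
        S3 = 7.3 * S
        _, q3, _ = max_modularity_partition(average_linkage_dendrogram(S3, names), S3)
        assert q1 == pytest.approx(q2, abs=1e-12)
        assert q1 == pytest.approx(q3, abs=1e-12)

    def test_disconnected_planted_blocks_are_recovered(self):
        S = planted_partition_matrix(3, 4.0, 0.0, [2, 3, 2])
        d = average_linkage_dendrogram(S)
        partition, q_max, _ = max_modularity_partition(d, S)
        labels = np.repeat([0, 1, 2], [2, 3, 2])
        groups = {}
        for i, cid in enumerate(partition[d.leaves[i]] for i in range(7)):
            groups.setdefault(cid, set()).add(labels[i])
        assert all(len(g) == 1 for g in groups.values()) and len(groups) == 3
        assert q_max > 0.3

    def test_q_bounds(self, rng):
        for n in (4, 5, 6):
            S = random_similarity(rng, n)
            d = average_linkage_dendrogram(S)
            _, q_max, q_by_cut = max_modularity_partition(d, S)
            assert -0.5 - 1e-12 <= min(q_by_cut) and q_max <= 1.0
            assert q_by_cut[-1] == pytest.approx(0.0, abs=1e-15)


class TestOutInRatios:
    def test_published_cluster_table_semantics(self):
        net = paper_like_network()
        partition = {"NE": 0, "C": 0, "NW": 1, "W": 1, "S": 2}
        ratios, in_c, out_c = out_in_ratios(net, partition)
        assert "S" not in ratios  # singleton clusters are excluded
        assert (in_c["NE"], out_c["NE"]) == (78, 34)
        assert ratios["NE"] == pytest.approx(34 / 78)
        assert ratios["C"] == pytest.approx(12 / 13)
        assert (in_c["NW"], out_c["NW"]) == (52, 8)
        assert ratios["W"] == pytest.approx(14 / 20)

    def test_no_outside_events_gives_zero(self):
        W = np.zeros((3, 3), dtype=int)
        W[0, 1] = 10
        net = DispersalNetwork(("a", "b", "c"), W, np.zeros(3, int))
        ratios, _, _ = out_in_ratios(net, {"a": 0, "b": 0, "c": 1})
        assert ratios["a"] == 0.0

    def test_no_inside_events_is_undefined(self):
        W = np.zeros((3, 3), dtype=int)
        W[0, 2] = 4
        net = DispersalNetwork(("a", "b", "c"), W, np.zeros(3, int))
        with pytest.warns(UserWarning, match="undefined"):
            ratios, _, _ = out_in_ratios(net, {"a": 0, "b": 0, "c": 1})
        assert ratios["a"] is None


def test_full_analysis_on_paper_like_network():
    # the NE/C and NW/W pairs must land in different clusters; the weakly
    # attached southern population may join either side of the tree
    cres = analyze_clusters(paper_like_network())
    part = cres.partition
    assert part["NE"] == part["C"]
    assert part["NW"] == part["W"]
    assert part["NE"] != part["NW"]
    assert cres.ccc is not None and cres.ccc > 0.8
    assert -0.5 <= cres.q_max <= 1.0
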