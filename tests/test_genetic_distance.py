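import math

import numpy as np
import pytest

from ucekit.genetic_distance import (
    DistanceMatrix,
    neighbor_joining,
    pairwise_distance,
    patristic,
    rank_base_candidates,
)


class TestPairwiseDistance:
    def test_identical_all_methods_zero(self):
        aln = {"a": "ACGTACGT", "b": "ACGTACGT"}
        for method in ("p", "JC69", "TN93"):
            assert pairwise_distance(aln, method).get("a", "b") == pytest.approx(0.0)

    def test_p_distance_quarter(self):
        assert pairwise_distance({"a": "ACGT", "b": "ACGA"}, "p").get("a", "b") == 0.25

    def test_jc69_formula(self):
        aln = {"a": "A" * 90 + "C" * 10, "b": "A" * 90 + "G" * 10}
        d = pairwise_distance(aln, "JC69").get("a", "b")
        assert d == pytest.approx(-0.75 * math.log(1 - 4 * 0.1 / 3))

    def test_jc69_ge_p(self, rng):
        for _ in range(20):
            n = 300
            a = "".join(rng.choice(list("ACGT"), size=n))
            b = list(a)
            for i in range(n):
                if rng.random() < 0.15:
                    b[i] = "ACGT"[int(rng.integers(4))]
            aln = {"a": a, "b": "".join(b)}
            p = pairwise_distance(aln, "p").get("a", "b")
            if 0 < p < 0.74:
                assert pairwise_distance(aln, "JC69").get("a", "b") >= p

    def test_tn93_against_formula_oracle(self):
        """100 sites: 10 A<->G transitions, 5 transversions, balanced bases."""
        a = ("ACGT" * 25)[:100]
        b = list(a)
        ag = [i for i, x in enumerate(a) if x == "A"][:10]
        for i in ag:
            b[i] = "G"
        tv = [i for i, x in enumerate(a) if x == "C"][:5]
        for i in tv:
            b[i] = "G"
        aln = {"a": a, "b": "".join(b)}
        d = pairwise_distance(aln, "TN93").get("a", "b")

        # independent closed-form evaluation from the site counts
        sites = list(zip(a, "".join(b)))
        n = len(sites)
        freq = {x: 0.0 for x in "ACGT"}
        for x, y in sites:
            freq[x] += 0.5 / n
            freq[y] += 0.5 / n
        gA, gC, gG, gT = (freq[x] for x in "ACGT")
        gR, gY = gA + gG, gC + gT
        p1 = sum(1 for x, y in sites if {x, y} == {"A", "G"}) / n
        p2 = sum(1 for x, y in sites if {x, y} == {"C", "T"}) / n
        q = sum(
            1 for x, y in sites if x != y and ((x in "AG") != (y in "AG"))
        ) / n
        w1 = 2 * gA * gG / gR
        w2 = 2 * gT * gC / gY
        w3 = 2 * (gR * gY - gA * gG * gY / gR - gT * gC * gR / gY)
        expected = (
            -w1 * math.log(1 - p1 / w1 - q / (2 * gR))
            - w2 * math.log(1 - p2 / w2 - q / (2 * gY))
            - w3 * math.log(1 - q / (2 * gR * gY))
        )
        assert d == pytest.approx(expected)
        assert d > pairwise_distance(aln, "p").get("a", "b")

    def test_pairwise_deletion(self):
        aln = {"a": "ACGT-N", "b": "ACGAAA"}
        d = pairwise_distance(aln, "p").get("a", "b")
        assert d == 0.25  # only 4 comparable sites, 1 mismatch

    def test_zero_comparable_sites_errors(self):
        with pytest.raises(ValueError):
            pairwise_distance({"a": "NNNN", "b": "ACGT"}, "p")

    def test_unaligned_errors(self):
        with pytest.raises(ValueError):
            pairwise_distance({"a": "ACGT", "b": "ACG"}, "p")

    def test_saturated_flagged(self):
        aln = {"a": "A" * 100, "b": "C" * 100}
        dm = pairwise_distance(aln, "JC69")
        assert math.isnan(dm.get("a", "b"))
        assert ("a", "b") in dm.saturated

    def test_matrix_invariants(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]), "p")
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[1.0, 0.0], [0.0, 0.0]]), "p")


def _tree_matrix(taxa, paths):
    n = len(taxa)
    m = np.zeros((n, n))
    for (i, j), d in paths.items():
        m[i, j] = m[j, i] = d
    return DistanceMatrix(taxa, m, "p")


class TestNeighborJoining:
    def test_three_taxa_additive_exact(self):
        # any 3-taxon matrix is additive: patristic must reproduce it
        dm = _tree_matrix(["a", "b", "c"], {(0, 1): 0.3, (0, 2): 0.5, (1, 2): 0.6})
        pat = patristic(neighbor_joining(dm))
        assert np.allclose(pat.matrix, dm.matrix, atol=1e-12)

    def test_four_taxon_known_tree(self):
        # tree ((a:1,b:2):3,(c:4,d:5)) -> path sums
        paths = {
            (0, 1): 3.0,  # a-b
            (0, 2): 8.0,  # a-(3)-(c:4)
            (0, 3): 9.0,
            (1, 2): 9.0,
            (1, 3): 10.0,
            (2, 3): 9.0,
        }
        dm = _tree_matrix(["a", "b", "c", "d"], paths)
        tree = neighbor_joining(dm)
        pat = patristic(tree)
        assert np.allclose(pat.matrix, dm.matrix, atol=1e-9)
        # topology check: a and b are siblings
        (a_parent,) = tree.adjacency["a"]
        assert "b" in tree.adjacency[a_parent]

    def test_ultrametric_four_taxa(self):
        paths = {
            (0, 1): 0.2,
            (0, 2): 0.6,
            (0, 3): 0.6,
            (1, 2): 0.6,
            (1, 3): 0.6,
            (2, 3): 0.4,
        }
        dm = _tree_matrix(["a", "b", "c", "d"], paths)
        assert np.allclose(patristic(neighbor_joining(dm)).matrix, dm.matrix, atol=1e-9)

    def test_random_additive_matrices_path_sum_oracle(self, rng):
        for _ in range(20):
            tree_adj, leaves = _random_tree(rng, int(rng.integers(4, 9)))
            dm = _path_sum_matrix(tree_adj, leaves)
            pat = patristic(neighbor_joining(dm))
            assert np.allclose(pat.matrix, dm.matrix, atol=1e-9)

    def test_agrees_with_skbio_on_additive(self, rng):
        skbio = pytest.importorskip("skbio")
        tree_adj, leaves = _random_tree(rng, 6)
        dm = _path_sum_matrix(tree_adj, leaves)
        sk_dm = skbio.DistanceMatrix(dm.matrix, ids=dm.taxa)
        sk_tree = skbio.tree.nj(sk_dm)
        ours = patristic(neighbor_joining(dm))
        for i, a in enumerate(dm.taxa):
            for b in dm.taxa[i + 1 :]:
                assert ours.get(a, b) == pytest.approx(
                    sk_tree.find(a).distance(sk_tree.find(b)), abs=1e-6
                )

    def test_needs_three(self):
        dm = _tree_matrix(["a", "b"], {(0, 1): 1.0})
        with pytest.raises(ValueError):
            neighbor_joining(dm)

    def test_negative_branch_clamped_flagged(self):
        m = np.array(
            [
                [0.0, 0.1, 0.6, 0.6],
                [0.1, 0.0, 0.6, 0.6],
                [0.6, 0.6, 0.0, 0.01],
                [0.6, 0.6, 0.01, 0.0],
            ]
        )
        dm = DistanceMatrix(["a", "b", "c", "d"], m, "p")
        tree = neighbor_joining(dm)
        for node, nbrs in tree.adjacency.items():
            for length in nbrs.values():
                assert length >= 0

    def test_newick_parses(self):
        dendropy = pytest.importorskip("dendropy")
        dm = _tree_matrix(["a", "b", "c"], {(0, 1): 0.3, (0, 2): 0.5, (1, 2): 0.6})
        nwk = neighbor_joining(dm).newick()
        t = dendropy.Tree.get(data=nwk, schema="newick")
        assert {l.taxon.label for l in t.leaf_node_iter()} == {"a", "b", "c"}


def _random_tree(rng, n_leaves):
    """Random unrooted binary tree with positive branch lengths."""
    nodes = [f"L{i}" for i in range(n_leaves)]
    adj = {}
    counter = 0
    active = nodes[:]
    while len(active) > 2:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[int(i)], active[int(j)]
        internal = f"I{counter}"
        counter += 1
        for x in (a, b):
            w = float(rng.uniform(0.05, 1.0))
            adj.setdefault(internal, {})[x] = w
            adj.setdefault(x, {})[internal] = w
        active = [x for x in active if x not in (a, b)] + [internal]
    a, b = active
    w = float(rng.uniform(0.05, 1.0))
    adj.setdefault(a, {})[b] = w
    adj.setdefault(b, {})[a] = w
    return adj, nodes


def _path_sum_matrix(adj, leaves):
    import collections

    n = len(leaves)
    m = np.zeros((n, n))
    for i, a in enumerate(leaves):
        dist = {a: 0.0}
        queue = collections.deque([a])
        while queue:
            node = queue.popleft()
            for nb, w in adj[node].items():
                if nb not in dist:
                    dist[nb] = dist[node] + w
                    queue.append(nb)
        for j, b in enumerate(leaves):
            m[i, j] = dist[b]
    np.fill_diagonal(m, 0.0)
    return DistanceMatrix(leaves, (m + m.T) / 2, "p")


class TestRanking:
    def test_single_matrix_closest_ranks_first(self):
        m = np.array(
            [
                [0.0, 0.1, 0.1],
                [0.1, 0.0, 0.3],
                [0.1, 0.3, 0.0],
            ]
        )
        dm = DistanceMatrix(["a", "b", "c"], m, "p")
        ranking = rank_base_candidates([dm])
        assert ranking.order[0] == "a"
        assert ranking.mean_rank["a"] == 1.0

    def test_marker_order_invariance(self, rng):
        mats = []
        for _ in range(4):
            tree_adj, leaves = _random_tree(rng, 5)
            mats.append(_path_sum_matrix(tree_adj, leaves))
        r1 = rank_base_candidates(mats)
        r2 = rank_base_candidates(list(reversed(mats)))
        assert r1.mean_rank == r2.mean_rank

    def test_ties_share_mean_rank(self):
        m = np.full((3, 3), 0.2)
        np.fill_diagonal(m, 0.0)
        ranking = rank_base_candidates([DistanceMatrix(["a", "b", "c"], m, "p")])
        assert all(v == 2.0 for v in ranking.mean_rank.values())

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            rank_base_candidates([])
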