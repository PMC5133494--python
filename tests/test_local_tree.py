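"""Window growth, UPGMA construction, cluster cuts and the implied covariance.

The brute-force oracles here are deliberately independent re-implementations
(full rescans of the distance matrix, explicit gamete enumeration, naive
replay of the window growth rule) so agreement is meaningful.
"""

import itertools

import numpy as np
import pytest

from treescan import (
    InvalidArgumentError,
    build_tree,
    covariance_from_clusters,
    cut_to_clusters,
    four_gamete_compatible,
    select_window,
    to_newick,
    upgma,
)
from treescan.tree import clustered_to_newick

from conftest import make_haps, random_haps


# ---------------------------------------------------------------- four gametes

class TestFourGametes:
    def test_reference_cases(self):
        assert not four_gamete_compatible([0, 0, 1, 1], [0, 1, 0, 1])
        col = [0, 1, 1, 0]
        assert four_gamete_compatible(col, col)

    def test_exhaustive_against_gamete_enumeration(self):
        """All 2^8 pairs of 4-row columns versus explicit pair counting."""
        for a in itertools.product((0, 1), repeat=4):
            for b in itertools.product((0, 1), repeat=4):
                gametes = {(x, y) for x, y in zip(a, b)}
                expected = len(gametes) < 4
                assert four_gamete_compatible(np.array(a), np.array(b)) == expected


# ------------------------------------------------------------ window selection

def replay_window(entries, focal, max_window):
    """Independent replay of the growth rule: alternate left/right from the
    focal SNP, admit a candidate only if compatible with the whole window,
    close a side at its first incompatible candidate."""

    def compat(i, j):
        pairs = set(zip(entries[:, i].tolist(), entries[:, j].tolist()))
        return len(pairs) < 4

    window = [focal]
    left, right = focal - 1, focal + 1
    open_sides = {"L": True, "R": True}
    side = "L"
    while len(window) < max_window and any(open_sides.values()):
        if side == "L":
            if open_sides["L"]:
                if left < 0 or not all(compat(left, w) for w in window):
                    open_sides["L"] = False
                else:
                    window.append(left)
                    left -= 1
            side = "R"
        else:
            if open_sides["R"]:
                if right >= entries.shape[1] or not all(compat(right, w) for w in window):
                    open_sides["R"] = False
                else:
                    window.append(right)
                    right += 1
            side = "L"
    return sorted(window)


class TestSelectWindow:
    def test_all_compatible_gives_centered_window(self):
        # identical columns are mutually compatible
        entries = np.tile(np.array([0, 1, 1, 0], dtype=np.uint8)[:, None], (1, 9))
        haps = make_haps(entries)
        assert list(select_window(haps, 4, 5)) == [2, 3, 4, 5, 6]

    def test_incompatible_neighbors_leave_singleton(self):
        incompat = np.array([0, 0, 1, 1], dtype=np.uint8)
        focal = np.array([0, 1, 0, 1], dtype=np.uint8)
        haps = make_haps(np.column_stack([incompat, focal, incompat]))
        assert list(select_window(haps, 1, 5)) == [1]

    def test_edge_focal_grows_one_sided(self):
        entries = np.tile(np.array([0, 1, 1, 0], dtype=np.uint8)[:, None], (1, 6))
        haps = make_haps(entries)
        assert list(select_window(haps, 0, 5)) == [0, 1, 2, 3, 4]

    def test_matches_independent_replay_on_random_matrices(self, rng):
        for _ in range(30):
            haps = random_haps(rng, n_individuals=8, n_snps=50, p=0.4)
            focal = int(rng.integers(0, 50))
            got = list(select_window(haps, focal, 21))
            assert got == replay_window(haps.entries, focal, 21)

    def test_rejects_even_window(self, small_gene):
        with pytest.raises(InvalidArgumentError):
            select_window(small_gene, 0, 4)


# ------------------------------------------------------------------------ UPGMA

def brute_force_upgma(D):
    """Naive UPGMA recomputing every cluster-pair average from the original
    distance matrix at each step; ties broken by the lowest (id_a, id_b)."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    clusters = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            total = sum(D[i, j] for i in clusters[a] for j in clusters[b])
            avg = total / (len(clusters[a]) * len(clusters[b]))
            key = (avg, a, b)
            if best is None or key < best:
                best = key
        avg, a, b = best
        merges.append((a, b, avg / 2.0))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


class TestUpgma:
    def test_three_tip_hand_example(self):
        # d(0,1)=2, d(0,2)=6, d(1,2)=6: first merge {0,1} at height 1, root at 3
        D = np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], dtype=float)
        tree = upgma(D)
        assert list(tree.children[0]) == [0, 1] and tree.heights[0] == 1.0
        assert list(tree.children[1]) == [2, 3] and tree.heights[1] == 3.0

    def test_identical_haplotypes_merge_at_height_zero(self):
        entries = np.array([[0, 1], [0, 1], [1, 0], [1, 1]], dtype=np.uint8)
        tree = build_tree(make_haps(entries), np.array([0, 1]))
        assert tree.heights[0] == 0.0
        assert list(tree.children[0]) == [0, 1]

    def test_matches_brute_force_on_random_integer_distances(self, rng):
        for _ in range(40):
            n = int(rng.integers(3, 8))
            half = rng.integers(0, 8, size=(n, n))
            D = (half + half.T).astype(float)
            np.fill_diagonal(D, 0)
            tree = upgma(D)
            expected = brute_force_upgma(D)
            for step, (a, b, h) in enumerate(expected):
                assert list(tree.children[step]) == sorted((a, b))
                assert tree.heights[step] == h  # exact: same rational arithmetic

    def test_deterministic_newick(self, small_gene):
        w = select_window(small_gene, 2, 11)
        t1, t2 = build_tree(small_gene, w), build_tree(small_gene, w)
        assert to_newick(t1) == to_newick(t2)

    def test_newick_parses_with_dendropy(self, small_gene):
        dendropy = pytest.importorskip("dendropy")
        w = select_window(small_gene, 0, 11)
        tree = build_tree(small_gene, w)
        parsed = dendropy.Tree.get(data=to_newick(tree), schema="newick")
        assert len(parsed.leaf_nodes()) == small_gene.n_chromosomes
        # ultrametric: all root-to-tip path lengths equal the tree height
        depths = [leaf.distance_from_root() for leaf in parsed.leaf_nodes()]
        assert np.allclose(depths, tree.total_height, atol=1e-6)


# ---------------------------------------------------------------- cluster cuts

def brute_force_cut(tree, k):
    """Remove the k-1 highest merges (later merge wins ties) and read the
    connected components off the remaining forest."""
    n = tree.n_tips
    order = sorted(range(n - 1), key=lambda m: (-tree.heights[m], -m))
    removed = set(order[: k - 1])
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(2 * n - 1))
    for m in range(n - 1):
        if m not in removed:
            g.add_edge(tree.children[m][0], n + m)
            g.add_edge(tree.children[m][1], n + m)
    comps = list(nx.connected_components(g))
    labels = {}
    for tip in range(n):
        for ci, comp in enumerate(comps):
            if tip in comp:
                labels[tip] = ci
    # canonical: partition as frozenset of frozensets
    part = {}
    for tip, lab in labels.items():
        part.setdefault(lab, set()).add(tip)
    return frozenset(frozenset(s) for s in part.values())


def partition_of(ct):
    part = {}
    for tip, lab in enumerate(ct.labels):
        part.setdefault(lab, set()).add(tip)
    return frozenset(frozenset(s) for s in part.values())


class TestCutToClusters:
    def test_k_equals_tip_count_gives_singletons(self, rng):
        haps = random_haps(rng, n_individuals=3, n_snps=8)
        tree = build_tree(haps, np.arange(8))
        ct = cut_to_clusters(tree, 6)
        assert ct.cluster_sizes().tolist() == [1] * 6

    def test_k2_gives_the_two_root_subtrees(self, rng):
        haps = random_haps(rng, n_individuals=4, n_snps=10)
        tree = build_tree(haps, np.arange(10))
        ct = cut_to_clusters(tree, 2)
        assert ct.k == 2
        assert partition_of(ct) == brute_force_cut(tree, 2)

    def test_matches_brute_force_removal(self, rng):
        for _ in range(25):
            haps = random_haps(rng, n_individuals=5, n_snps=12)
            tree = build_tree(haps, np.arange(12))
            k = int(rng.integers(2, 10))
            assert partition_of(cut_to_clusters(tree, k)) == brute_force_cut(tree, k)

    def test_partitions_nest_as_k_grows(self, rng):
        for _ in range(10):
            haps = random_haps(rng, n_individuals=6, n_snps=10)
            tree = build_tree(haps, np.arange(10))
            prev = partition_of(cut_to_clusters(tree, 2))
            for k in range(3, 8):
                cur = partition_of(cut_to_clusters(tree, k))
                # each current cluster lies inside one previous cluster
                for cl in cur:
                    assert any(cl <= big for big in prev)
                prev = cur

    def test_k_out_of_range(self, rng):
        haps = random_haps(rng, n_individuals=3, n_snps=6)
        tree = build_tree(haps, np.arange(6))
        for bad in (1, 7):
            with pytest.raises(InvalidArgumentError):
                cut_to_clusters(tree, bad)


# ------------------------------------------------------------------ covariance

class TestCovariance:
    def test_two_cluster_hand_example(self):
        # clusters {0,1} and {2,3}, cluster roots at height 1, root at 3:
        # within = (3-1)/3 = 2/3, between = (3-3)/3 = 0
        D = np.array(
            [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 2], [6, 6, 2, 0]], dtype=float
        )
        tree = upgma(D)
        ct = cut_to_clusters(tree, 2)
        V = covariance_from_clusters(ct, ridge=0.0).V
        expected = np.array(
            [
                [1, 2 / 3, 0, 0],
                [2 / 3, 1, 0, 0],
                [0, 0, 1, 2 / 3],
                [0, 0, 2 / 3, 1],
            ]
        )
        assert np.allclose(V, expected)

    def test_equal_height_merges_give_identity_covariance(self):
        # all pairwise distances equal: cluster roots coincide with the root
        D = np.full((4, 4), 2.0)
        np.fill_diagonal(D, 0)
        tree = upgma(D)
        V = covariance_from_clusters(cut_to_clusters(tree, 2)).V
        assert np.allclose(V, np.eye(4))

    def test_random_clustered_trees_valid_covariance(self, rng):
        """Symmetric, unit diagonal, off-diagonal in [0, 1), positive definite,
        within-cluster entries >= between-cluster entries."""
        for _ in range(60):
            haps = random_haps(rng, n_individuals=6, n_snps=12)
            tree = build_tree(haps, np.arange(12))
            if tree.total_height == 0:
                continue
            k = int(rng.integers(2, 9))
            ct = cut_to_clusters(tree, k)
            V = covariance_from_clusters(ct).V
            assert np.allclose(V, V.T)
            assert np.allclose(np.diag(V), 1.0)
            off = V[~np.eye(V.shape[0], dtype=bool)]
            assert np.all(off >= 0) and np.all(off < 1)
            assert np.linalg.eigvalsh(V).min() > 0
            labels = ct.labels
            for c in range(k):
                for d in range(c + 1, k):
                    within_c = V[np.ix_(labels == c, labels == c)]
                    within_d = V[np.ix_(labels == d, labels == d)]
                    between = V[np.ix_(labels == c, labels == d)]
                    floor_c = within_c.min() if within_c.size > 1 else 1.0
                    floor_d = within_d.min() if within_d.size > 1 else 1.0
                    assert between.max() <= min(floor_c, floor_d) + 1e-12

    def test_clustered_newick_parses(self, small_gene):
        dendropy = pytest.importorskip("dendropy")
        tree = build_tree(small_gene, select_window(small_gene, 1, 11))
        ct = cut_to_clusters(tree, 4)
        parsed = dendropy.Tree.get(data=clustered_to_newick(ct, tree), schema="newick")
        assert len(parsed.leaf_nodes()) == small_gene.n_chromosomes
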