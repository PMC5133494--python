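"""Per-SNP local phylogenies and the trait covariance they imply.

At each focal SNP a window of neighboring, mutually four-gamete-compatible
SNPs is selected; an average-linkage (UPGMA) tree over all chromosomes is
built from Hamming distances on that window; the tree is cut into its k
broad-scale clusters (the k - 1 earliest, i.e. deepest, splits); and the
clustered tree defines a trait covariance V with unit diagonal whose
off-diagonal entries are the shared root-to-MRCA branch fraction.

The UPGMA here is deliberately hand-rolled: average cluster distances are
tracked as exact integer cross-pair sums divided once, and ties are broken
by the lowest pair of cluster indices, so the whole construction is bitwise
reproducible and exactly checkable against a brute-force replay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import HaplotypeMatrix
from .errors import DegenerateTreeError, InvalidArgumentError

__all__ = [
    "LocalTree",
    "ClusteredTree",
    "CovarianceModel",
    "four_gamete_compatible",
    "select_window",
    "build_tree",
    "upgma",
    "cut_to_clusters",
    "covariance_from_clusters",
    "to_newick",
    "clustered_to_newick",
]

#: Default ridge weight guarding V against exact singularity from duplicated
#: haplotype rows.
DEFAULT_RIDGE = 1e-6

#: Default maximum window size (SNP count, odd) for local tree estimation.
DEFAULT_MAX_WINDOW = 21


@dataclass(frozen=True)
class LocalTree:
    """An ultrametric binary tree over chromosome rows.

    The ``m``-th merge creates node ``n_tips + m`` at height ``heights[m]``
    (measured from the tips) joining the subtrees rooted at node ids
    ``children[m]`` (stored sorted ascending).  Average linkage is monotone,
    so heights are non-decreasing in merge order.
    """

    children: np.ndarray  # (n_tips - 1, 2) node ids
    heights: np.ndarray  # (n_tips - 1,) merge heights from tips
    tip_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        children = np.asarray(self.children, dtype=np.int64)
        heights = np.asarray(self.heights, dtype=np.float64)
        object.__setattr__(self, "children", children)
        object.__setattr__(self, "heights", heights)
        object.__setattr__(self, "tip_ids", tuple(self.tip_ids))
        n = len(self.tip_ids)
        if children.shape != (n - 1, 2) or heights.shape != (n - 1,):
            raise InvalidArgumentError("tree needs exactly n_tips - 1 merges")
        if np.any(heights < 0):
            raise InvalidArgumentError("merge heights must be non-negative")
        if n > 2 and np.any(np.diff(heights) < -1e-9):
            raise InvalidArgumentError("merge heights must be non-decreasing (monotone linkage)")

    @property
    def n_tips(self) -> int:
        return len(self.tip_ids)

    @property
    def total_height(self) -> float:
        return float(self.heights[-1])


@dataclass(frozen=True)
class ClusteredTree:
    """The broad-scale k-cluster cut of a local tree.

    ``labels`` maps each tip to a cluster in ``0..k-1`` (numbered by first
    tip occurrence).  ``node_heights`` is the k x k matrix of heights: the
    diagonal holds each cluster's root height (0 for singleton clusters), the
    off-diagonal the height of the retained node where two clusters join.
    ``total_height`` is the root height H of the underlying tree.
    """

    k: int
    labels: np.ndarray
    node_heights: np.ndarray
    total_height: float
    tip_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=np.int64))
        object.__setattr__(self, "node_heights", np.asarray(self.node_heights, dtype=np.float64))
        object.__setattr__(self, "tip_ids", tuple(self.tip_ids))

    @property
    def n_tips(self) -> int:
        return self.labels.shape[0]

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


@dataclass(frozen=True)
class CovarianceModel:
    """V(theta): the n x n trait covariance implied by a clustered tree."""

    V: np.ndarray
    k: int
    snp_index: int | None = None


def four_gamete_compatible(col_a: np.ndarray, col_b: np.ndarray) -> bool:
    """Two biallelic columns fit on one tree iff not all four gametes occur.

    Returns False exactly when all of {00, 01, 10, 11} appear across rows.
    The check is invariant to complementing either column, so allele
    orientation does not matter.
    """
    a = np.asarray(col_a, dtype=np.int64)
    b = np.asarray(col_b, dtype=np.int64)
    if a.shape != b.shape:
        raise InvalidArgumentError("columns must have equal length")
    return np.unique(2 * a + b).size < 4


def select_window(haps: HaplotypeMatrix, focal: int, max_window: int = DEFAULT_MAX_WINDOW) -> np.ndarray:
    """Grow the four-gamete-compatible SNP window around a focal SNP.

    Starting from {focal}, candidates are taken alternately from the nearest
    unused SNP on the left and right.  A candidate joins only if it is
    compatible with every SNP already in the window; the first incompatible
    candidate on a side stops that side permanently.  Growth ends when both
    sides have stopped or the window holds ``max_window`` SNPs.  Returns the
    selected indices sorted ascending (always containing ``focal``).
    """
    if not 0 <= focal < haps.n_snps:
        raise InvalidArgumentError(f"focal index {focal} out of range")
    if max_window < 1 or max_window % 2 == 0:
        raise InvalidArgumentError("max_window must be odd and >= 1")
    entries = haps.entries
    window = [focal]
    left, right = focal - 1, focal + 1
    left_open, right_open = True, True
    turn_left = True
    while len(window) < max_window and (left_open or right_open):
        if turn_left:
            if left_open:
                if left < 0:
                    left_open = False
                elif all(four_gamete_compatible(entries[:, left], entries[:, w]) for w in window):
                    window.append(left)
                    left -= 1
                else:
                    left_open = False
            turn_left = False
        else:
            if right_open:
                if right >= haps.n_snps:
                    right_open = False
                elif all(four_gamete_compatible(entries[:, right], entries[:, w]) for w in window):
                    window.append(right)
                    right += 1
                else:
                    right_open = False
            turn_left = True
    return np.asarray(sorted(window), dtype=np.int64)


def upgma(distances: np.ndarray, tip_ids: tuple[str, ...] | None = None) -> LocalTree:
    """Average-linkage agglomeration with exact, reproducible tie handling.

    Merge heights are half the average-linkage distance.  Cluster ids are
    tips ``0..n-1`` then new nodes ``n, n+1, ...``; among equally distant
    pairs the lexicographically lowest (id_a, id_b) pair merges first.
    Cross-cluster distances are stored as sums and divided once, so two
    mathematically equal averages compare equal in floating point.
    """
    D = np.asarray(distances, dtype=np.float64)
    n = D.shape[0]
    if D.shape != (n, n):
        raise InvalidArgumentError("distance matrix must be square")
    if n < 2:
        raise InvalidArgumentError("need at least 2 tips")
    if tip_ids is None:
        tip_ids = tuple(str(i) for i in range(n))
    pair_sum = D.copy()
    sizes = np.ones(n)
    slot_id = np.arange(n)
    active = np.ones(n, dtype=bool)
    children = np.empty((n - 1, 2), dtype=np.int64)
    heights = np.empty(n - 1)
    for step in range(n - 1):
        avg = pair_sum / np.outer(sizes, sizes)
        avg[~active, :] = np.inf
        avg[:, ~active] = np.inf
        np.fill_diagonal(avg, np.inf)
        d = avg.min()
        ii, jj = np.nonzero(avg == d)
        upper = ii < jj
        ii, jj = ii[upper], jj[upper]
        id_lo = np.minimum(slot_id[ii], slot_id[jj])
        id_hi = np.maximum(slot_id[ii], slot_id[jj])
        best = np.lexsort((id_hi, id_lo))[0]
        i, j = int(ii[best]), int(jj[best])
        children[step] = (id_lo[best], id_hi[best])
        heights[step] = d / 2.0
        merged = pair_sum[i] + pair_sum[j]
        pair_sum[i, :] = merged
        pair_sum[:, i] = merged
        pair_sum[i, i] = 0.0
        sizes[i] += sizes[j]
        active[j] = False
        slot_id[i] = n + step
    return LocalTree(children=children, heights=heights, tip_ids=tip_ids)


def build_tree(haps: HaplotypeMatrix, window: np.ndarray) -> LocalTree:
    """UPGMA tree over all chromosomes from Hamming distances on a SNP window."""
    window = np.asarray(window, dtype=np.int64)
    if window.size == 0:
        raise InvalidArgumentError("window must be non-empty")
    X = haps.entries[:, window].astype(np.int64)
    s = X.sum(axis=1)
    D = (s[:, None] + s[None, :] - 2 * (X @ X.T)).astype(np.float64)
    return upgma(D, tip_ids=haps.chromosome_ids())


def cut_to_clusters(tree: LocalTree, k: int) -> ClusteredTree:
    """Cut a local tree into the k clusters below its k - 1 earliest splits.

    The retained nodes are the k - 1 highest internal nodes; because average
    linkage is monotone these are exactly the last k - 1 merges, which also
    implements the tie rule that among equal heights the later merge is the
    earlier split.
    """
    n = tree.n_tips
    if not 2 <= k <= n:
        raise InvalidArgumentError(f"k must be in [2, {n}], got {k}")
    n_merges = n - 1
    cut = n_merges - (k - 1)

    parent = np.arange(n + n_merges, dtype=np.int64)

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    for m in range(cut):
        a, b = tree.children[m]
        node = n + m
        parent[find(a)] = node
        parent[find(b)] = node

    labels = np.empty(n, dtype=np.int64)
    order: dict[int, int] = {}
    root_of_label: dict[int, int] = {}
    for t in range(n):
        r = find(t)
        if r not in order:
            order[r] = len(order)
            root_of_label[r] = order[r]
        labels[t] = order[r]
    if len(order) != k:
        raise DegenerateTreeError(f"cut produced {len(order)} clusters, expected {k}")

    cluster_heights = np.zeros(k)
    for r, lab in order.items():
        cluster_heights[lab] = 0.0 if r < n else tree.heights[r - n]

    node_heights = np.zeros((k, k))
    np.fill_diagonal(node_heights, cluster_heights)
    members: dict[int, list[int]] = {r: [lab] for r, lab in order.items()}
    for m in range(cut, n_merges):
        a, b = tree.children[m]
        ra, rb = find(int(a)), find(int(b))
        la, lb = members.pop(ra), members.pop(rb)
        h = tree.heights[m]
        for c in la:
            for d in lb:
                node_heights[c, d] = node_heights[d, c] = h
        node = n + m
        parent[ra] = node
        parent[rb] = node
        members[node] = la + lb

    return ClusteredTree(
        k=k,
        labels=labels,
        node_heights=node_heights,
        total_height=tree.total_height,
        tip_ids=tree.tip_ids,
    )


def covariance_from_clusters(
    ct: ClusteredTree,
    ridge: float = DEFAULT_RIDGE,
    snp_index: int | None = None,
) -> CovarianceModel:
    """Build V from a clustered tree.

    For tips a != b, ``V_ab = (H - h(MRCA)) / H`` where h is measured from
    the tips and same-cluster pairs use the cluster root; ``V_aa = 1``.
    Normalizing the shared branch length by the total height H fixes the
    proportionality constant, making sigma^2 the single scale parameter.
    A ridge ``V <- (1 - ridge) V + ridge I`` guards against exact
    singularity from duplicated haplotypes while keeping the unit diagonal.
    """
    if ct.total_height <= 0:
        raise DegenerateTreeError("tree has zero height; covariance undefined")
    W = (ct.total_height - ct.node_heights) / ct.total_height
    V = W[np.ix_(ct.labels, ct.labels)]
    np.fill_diagonal(V, 1.0)
    if ridge:
        V = (1.0 - ridge) * V + ridge * np.eye(ct.n_tips)
    return CovarianceModel(V=V, k=ct.k, snp_index=snp_index)


def _node_newick(tree: LocalTree, node: int, parent_height: float) -> str:
    n = tree.n_tips
    if node < n:
        label = tree.tip_ids[node]
        return f"{label}:{parent_height:.10g}"
    m = node - n
    h = tree.heights[m]
    parts = ",".join(_node_newick(tree, int(c), h) for c in tree.children[m])
    return f"({parts}):{parent_height - h:.10g}"


def to_newick(tree: LocalTree) -> str:
    """Newick string with branch lengths; tip labels are chromosome ids."""
    root = tree.n_tips + tree.n_tips - 2
    m = root - tree.n_tips
    h = tree.heights[m]
    parts = ",".join(_node_newick(tree, int(c), h) for c in tree.children[m])
    return f"({parts});"


def clustered_to_newick(ct: ClusteredTree, tree: LocalTree) -> str:
    """Newick for the clustered tree: each cluster collapsed to a
    multifurcation of its tips at the cluster root height."""
    import sys

    sys.setrecursionlimit(max(sys.getrecursionlimit(), 10 * ct.n_tips + 100))
    H = ct.total_height
    # cluster subtrees as flat multifurcations
    cluster_strs = []
    for c in range(ct.k):
        tips = np.flatnonzero(ct.labels == c)
        h = ct.node_heights[c, c]
        if tips.size == 1:
            cluster_strs.append((c, f"{ct.tip_ids[int(tips[0])]}"))
        else:
            inner = ",".join(f"{ct.tip_ids[int(t)]}:{h:.10g}" for t in tips)
            cluster_strs.append((c, f"({inner})"))
    # join clusters following the retained-node heights, nearest pairs first
    nodes: dict[int, tuple[str, float]] = {c: (s, ct.node_heights[c, c]) for c, s in cluster_strs}
    pairs = sorted(
        ((ct.node_heights[c, d], c, d) for c in range(ct.k) for d in range(c + 1, ct.k)),
        key=lambda x: (x[0], x[1], x[2]),
    )
    comp = {c: c for c in range(ct.k)}

    def croot(c: int) -> int:
        while comp[c] != c:
            c = comp[c]
        return c

    for h, c, d in pairs:
        rc, rd = croot(c), croot(d)
        if rc == rd:
            continue
        sc, hc = nodes.pop(rc)
        sd, hd = nodes.pop(rd)
        merged = f"({sc}:{h - hc:.10g},{sd}:{h - hd:.10g})"
        comp[rd] = rc
        nodes[rc] = (merged, h)
    (s, _), = nodes.values()
    return s + ";"
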