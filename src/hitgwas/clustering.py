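"""Genome-wide hierarchical clustering of markers by correlation.

Markers are clustered on the dissimilarity d(i, j) = 1 - |Pearson r|:
anti-correlated markers explain a phenotype equally well up to sign, so
they must end up in the same cluster.  The clustering is genome-wide
(never per chromosome) because population structure correlates
physically unlinked markers, and a result cluster may legitimately
combine two distant regions that cannot be statistically distinguished.

For p up to ``max_partition_size`` the tree is the exact average-linkage
agglomeration of the full dissimilarity matrix.  Beyond that an O(p^2)
matrix is no longer practical, so a two-stage scheme is used: a seeded
k-medoids pass partitions markers into blocks of at most
``max_partition_size``, each block is agglomerated exactly, and the
block roots are joined by agglomerating the block medoids, with heights
monotonized so that every parent is at least as high as its children.
Every node of the resulting tree is a candidate cluster for the
hierarchical association test.
"""

from __future__ import annotations

import json

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

__all__ = [
    "MarkerHierarchy",
    "marker_dissimilarity",
    "build_hierarchy",
    "cluster_medoid",
    "cut_children",
]


def _standardize(values: np.ndarray) -> np.ndarray:
    sd = values.std(axis=0)
    if (sd == 0).any():
        j = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"zero-variance marker column {j}; deduplicate first")
    return (values - values.mean(axis=0)) / sd


def _abs_corr(Z: np.ndarray, idx_a=None, idx_b=None) -> np.ndarray:
    A = Z if idx_a is None else Z[:, idx_a]
    B = Z if idx_b is None else Z[:, idx_b]
    C = np.abs(A.T @ B / Z.shape[0])
    return np.clip(C, 0.0, 1.0)


def marker_dissimilarity(G, i: int, j: int) -> float:
    """1 - |Pearson correlation| between marker columns i and j."""
    x = G.values[:, i]
    y = G.values[:, j]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance marker in dissimilarity")
    r = np.corrcoef(x, y)[0, 1]
    return float(1.0 - abs(r))


class MarkerHierarchy:
    """Binary tree over marker indices.

    Node ids 0..p-1 are the leaves (leaf i = marker i); internal nodes
    follow.  Each node has a height in [0, 1] (leaves at 0), its member
    marker indices, and a parent (-1 for the root).
    """

    def __init__(self, parent, children, height, members, n_markers):
        self.parent = np.asarray(parent, dtype=int)
        self.children = [list(c) for c in children]
        self.height = np.asarray(height, dtype=float)
        self.members = [np.asarray(m, dtype=int) for m in members]
        self.n_markers = int(n_markers)
        self._medoid_cache: dict[int, int] = {}

    # -- structure -----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    def is_leaf(self, node_id: int) -> bool:
        return node_id < self.n_markers

    def node_members(self, node_id: int) -> np.ndarray:
        self._check(node_id)
        return self.members[node_id]

    def _check(self, node_id: int):
        if not (0 <= node_id < self.n_nodes):
            raise KeyError(f"no node {node_id} in hierarchy")

    def top_down_order(self) -> list[int]:
        """Node ids such that every parent precedes its children."""
        order = [self.root]
        i = 0
        while i < len(order):
            order.extend(self.children[order[i]])
            i += 1
        return order

    def medoid(self, G, node_id: int) -> int:
        """Marker index minimizing total dissimilarity to the other
        members; ties go to the earliest marker in genome order."""
        self._check(node_id)
        if node_id not in self._medoid_cache:
            self._medoid_cache[node_id] = cluster_medoid(G, self.members[node_id])
        return self._medoid_cache[node_id]

    def validate(self) -> None:
        """Assert the tree invariants (partition, height monotonicity)."""
        root = self.root
        assert sorted(self.members[root].tolist()) == list(range(self.n_markers))
        assert np.all(self.height[: self.n_markers] == 0.0)
        for node in range(self.n_nodes):
            kids = self.children[node]
            if self.is_leaf(node):
                assert not kids and self.members[node].tolist() == [node]
                continue
            assert kids, f"internal node {node} without children"
            merged = np.concatenate([self.members[k] for k in kids])
            assert len(merged) == len(set(merged.tolist()))
            assert sorted(merged.tolist()) == sorted(self.members[node].tolist())
            for k in kids:
                assert self.parent[k] == node
                assert self.height[k] <= self.height[node] + 1e-9

    # -- serialization ---------------------------------------------------
    def to_newick(self, marker_ids=None) -> str:
        """Newick string; branch lengths encode height differences."""
        names = marker_ids or [f"m{i}" for i in range(self.n_markers)]

        def rec(node):
            bl = (self.height[self.parent[node]] - self.height[node]
                  if self.parent[node] != -1 else 0.0)
            if self.is_leaf(node):
                return f"{names[node]}:{bl:.10g}"
            inner = ",".join(rec(k) for k in cut_children(self, node))
            return f"({inner})n{node}:{bl:.10g}"

        return rec(self.root) + ";"

    def to_json(self) -> str:
        return json.dumps({
            "n_markers": self.n_markers,
            "parent": self.parent.tolist(),
            "children": self.children,
            "height": self.height.tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "MarkerHierarchy":
        d = json.loads(text)
        p = d["n_markers"]
        n_nodes = len(d["parent"])
        members: list = [None] * n_nodes
        root = d["parent"].index(-1)
        # postorder fill so children are resolved before their parent
        stack = [(root, False)]
        while stack:
            node, expanded = stack.pop()
            if node < p:
                members[node] = [node]
                continue
            if expanded:
                members[node] = sorted(
                    x for k in d["children"][node] for x in members[k])
            else:
                stack.append((node, True))
                stack.extend((k, False) for k in d["children"][node])
        return cls(d["parent"], d["children"], d["height"], members, p)

    @classmethod
    def from_linkage(cls, Z: np.ndarray, p: int) -> "MarkerHierarchy":
        """Build from a scipy linkage matrix over p observations."""
        n_nodes = p + len(Z)
        parent = np.full(n_nodes, -1, dtype=int)
        children: list[list[int]] = [[] for _ in range(n_nodes)]
        height = np.zeros(n_nodes)
        members: list = [np.array([i]) for i in range(p)] + [None] * len(Z)
        for i, row in enumerate(Z):
            node = p + i
            a, b = int(row[0]), int(row[1])
            parent[a] = parent[b] = node
            children[node] = [a, b]
            height[node] = min(max(row[2], 0.0), 1.0)
            members[node] = np.sort(np.concatenate([members[a], members[b]]))
        # enforce monotone heights (average linkage is monotone; guard fp noise)
        for i in range(len(Z)):
            node = p + i
            hmax = max(height[k] for k in children[node])
            height[node] = max(height[node], hmax)
        return cls(parent, children, height, members, p)


def cluster_medoid(G, member_indices) -> int:
    """Member marker minimizing the sum of 1-|r| dissimilarities to the
    other members; ties broken by genome order (lowest marker index)."""
    member_indices = np.asarray(member_indices, dtype=int)
    if member_indices.size == 0:
        raise ValueError("empty member set")
    if member_indices.size == 1:
        return int(member_indices[0])
    member_indices = np.sort(member_indices)
    Z = _standardize(G.values[:, member_indices])
    D = 1.0 - _abs_corr(Z)
    np.fill_diagonal(D, 0.0)
    sums = D.sum(axis=1)
    return int(member_indices[int(np.argmin(sums))])


def cut_children(H: MarkerHierarchy, node_id: int) -> list[int]:
    """Children of a node, ordered by their smallest member index;
    empty for leaves."""
    H._check(node_id)
    return sorted(H.children[node_id], key=lambda k: int(H.members[k][0]))


# ---------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------

def build_hierarchy(G, max_partition_size: int = 2000, seed: int = 0) -> MarkerHierarchy:
    """Hierarchical clustering of all markers of ``G`` (deduplicated,
    imputed).  Exact average linkage when p <= max_partition_size,
    otherwise the two-stage partition scheme.  Deterministic given the
    matrix and ``seed``."""
    p = G.p_markers
    if p == 0:
        raise ValueError("no markers to cluster")
    if p == 1:
        return MarkerHierarchy([-1], [[]], [0.0], [[0]], 1)
    Z = _standardize(G.values)
    if p <= max_partition_size:
        return _exact_tree(Z)
    return _two_stage_tree(Z, max_partition_size, seed)


def _exact_tree(Z: np.ndarray, index=None) -> MarkerHierarchy:
    D = 1.0 - _abs_corr(Z if index is None else Z[:, index])
    np.fill_diagonal(D, 0.0)
    Zl = linkage(squareform(D, checks=False), method="average")
    return MarkerHierarchy.from_linkage(Zl, D.shape[0])


def _coarse_partition(Z: np.ndarray, idx: np.ndarray, max_size: int,
                      rng: np.random.Generator) -> list[np.ndarray]:
    """Split marker indices into blocks of at most ``max_size`` by a
    sampled k-medoids pass on 1-|r|; recursive bisection of oversized
    blocks guarantees the size bound."""
    m = len(idx)
    if m <= max_size:
        return [idx]
    k = max(2, int(np.ceil(m / max_size)))
    medoids = np.sort(rng.choice(idx, size=k, replace=False))
    for _ in range(3):
        D = 1.0 - _abs_corr(Z, idx, medoids)          # m x k
        assign = np.argmin(D, axis=1)
        new_medoids = medoids.copy()
        for c in range(k):
            block = idx[assign == c]
            if block.size == 0:
                continue
            ref = block if block.size <= 400 else np.sort(
                rng.choice(block, size=400, replace=False))
            sums = (1.0 - _abs_corr(Z, block, ref)).sum(axis=1)
            new_medoids[c] = block[int(np.argmin(sums))]
        if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
            medoids = new_medoids
            break
        medoids = new_medoids
    D = 1.0 - _abs_corr(Z, idx, medoids)
    assign = np.argmin(D, axis=1)
    out: list[np.ndarray] = []
    for c in range(k):
        block = idx[assign == c]
        if block.size == 0:
            continue
        if block.size > max_size:
            out.extend(_coarse_partition(Z, block, max_size, rng))
        else:
            out.append(block)
    return out


def _two_stage_tree(Z: np.ndarray, max_size: int, seed: int) -> MarkerHierarchy:
    p = Z.shape[1]
    rng = np.random.default_rng(seed)
    blocks = _coarse_partition(Z, np.arange(p), max_size, rng)
    blocks.sort(key=lambda b: int(b[0]))

    parent = np.full(p, -1, dtype=int)
    children: list[list[int]] = [[] for _ in range(p)]
    height = [0.0] * p
    members: list = [np.array([i]) for i in range(p)]

    def add_node(kids: list[int], h: float) -> int:
        node = len(parent_list)
        for k in kids:
            parent_list[k] = node
        parent_list.append(-1)
        children.append(list(kids))
        height.append(h)
        members.append(np.sort(np.concatenate([members[k] for k in kids])))
        return node

    parent_list = list(parent)
    block_roots: list[int] = []
    block_medoids: list[int] = []
    for block in blocks:
        if block.size == 1:
            block_roots.append(int(block[0]))
            block_medoids.append(int(block[0]))
            continue
        sub = _exact_tree(Z, block)
        # splice subtree nodes (leaves map to global marker ids)
        local_to_global = {i: int(block[i]) for i in range(block.size)}
        for local in range(block.size, sub.n_nodes):
            kids = [local_to_global[k] for k in sub.children[local]]
            local_to_global[local] = add_node(kids, float(sub.height[local]))
        block_roots.append(local_to_global[sub.root])
        Dsub = 1.0 - _abs_corr(Z, block, block)
        np.fill_diagonal(Dsub, 0.0)
        block_medoids.append(int(block[int(np.argmin(Dsub.sum(axis=1)))]))

    if len(block_roots) == 1:
        top_root = block_roots[0]
    else:
        med = np.asarray(block_medoids, dtype=int)
        Dm = 1.0 - _abs_corr(Z, med, med)
        np.fill_diagonal(Dm, 0.0)
        Zl = linkage(squareform(Dm, checks=False), method="average")
        node_of = {i: block_roots[i] for i in range(len(block_roots))}
        for i, row in enumerate(Zl):
            a, b = node_of[int(row[0])], node_of[int(row[1])]
            h = min(max(float(row[2]), 0.0), 1.0)
            h = max(h, height[a], height[b])   # monotone splice
            node_of[len(block_roots) + i] = add_node([a, b], h)
        top_root = node_of[len(block_roots) + len(Zl) - 1]

    H = MarkerHierarchy(parent_list, children, height, members, p)
    assert H.root == top_root
    return H
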