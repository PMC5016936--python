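"""p-distance matrices, neighbor joining and column-resampling bootstrap.

Trees are unrooted (serialized with an arbitrary trifurcating root);
downstream comparisons should use split sets, not rooted shapes.  Negative
neighbor-joining branch lengths are clamped to zero and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "PhyloTree",
    "p_distance_matrix",
    "nj_tree",
    "bootstrap_support",
]

_BASES = frozenset("ACGT")
MIN_OVERLAP = 30


@dataclass
class DistanceMatrix:
    labels: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise InputError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise InputError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0):
            raise InputError("diagonal must be zero")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise InputError("distances must be finite and non-negative")


@dataclass
class TreeNode:
    name: str | None = None
    children: list = field(default_factory=list)  # (TreeNode, branch_length)
    support: float | None = None

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list:
        if self.is_leaf():
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def newick(self) -> str:
        return self._newick() + ";"

    def _newick(self) -> str:
        if self.is_leaf():
            return self.name
        inner = ",".join(
            f"{c._newick()}:{bl:.6f}" for c, bl in self.children
        )
        label = "" if self.support is None else f"{self.support:.2f}"
        return f"({inner}){label}"


@dataclass
class PhyloTree:
    root: TreeNode
    labels: list
    negative_branches_clamped: int = 0
    supports: dict = field(default_factory=dict)  # bipartition -> fraction

    def newick(self) -> str:
        return self.root.newick()

    def splits(self) -> set:
        """Non-trivial bipartitions as frozensets of the smaller side."""
        n = len(self.labels)
        full = frozenset(self.labels)
        out = set()

        def walk(node: TreeNode) -> frozenset:
            if node.is_leaf():
                return frozenset([node.name])
            below = frozenset()
            for child, _ in node.children:
                sub = walk(child)
                if 2 <= len(sub) <= n - 2:
                    other = full - sub
                    out.add(min(sub, other, key=lambda s: (len(s), sorted(s))))
                below |= sub
            return below

        walk(self.root)
        return out

    def _edges_below(self) -> list:
        """(node, leafset-below) for internal edges, in traversal order."""
        n = len(self.labels)
        out = []

        def walk(node: TreeNode) -> frozenset:
            if node.is_leaf():
                return frozenset([node.name])
            below = frozenset()
            for child, _ in node.children:
                sub = walk(child)
                if not child.is_leaf() and 2 <= len(sub) <= n - 2:
                    out.append((child, sub))
                below |= sub
            return below

        walk(self.root)
        return out


def p_distance_matrix(
    column_strings: list, labels: list, min_overlap: int = MIN_OVERLAP
) -> DistanceMatrix:
    """Pairwise p-distances with pairwise deletion over shared columns."""
    if len(column_strings) < 3:
        raise InputError("need at least 3 sequences")
    if len(column_strings) != len(labels):
        raise InputError("labels/sequences length mismatch")
    L = len(column_strings[0])
    if any(len(s) != L for s in column_strings):
        raise InputError("column strings must have equal length")
    codes = np.zeros((len(column_strings), L), dtype=np.int8)
    lut = {"A": 1, "C": 2, "G": 3, "T": 4}
    for i, s in enumerate(column_strings):
        codes[i] = [lut.get(c, 0) for c in s]
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (codes[i] > 0) & (codes[j] > 0)
            shared = int(both.sum())
            if shared < min_overlap:
                raise InputError(
                    f"insufficient overlap between {labels[i]} and {labels[j]}"
                    f" ({shared} shared columns)"
                )
            mism = int(((codes[i] != codes[j]) & both).sum())
            values[i, j] = values[j, i] = mism / shared
    return DistanceMatrix(list(labels), values)


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are resolved toward the pair with the
    lexicographically smallest (cluster-minimum-label) pair.
    """
    n = len(dm.labels)
    if n < 3:
        raise InputError("need at least 3 taxa")
    D = dm.values.copy()
    nodes = [TreeNode(name=lab) for lab in dm.labels]
    minlab = list(dm.labels)
    active = list(range(n))
    clamped = 0

    import math

    while len(active) > 3:
        r = len(active)
        # fsum keeps R independent of summation order, so tie-breaking (and
        # therefore the tree) is invariant to leaf permutation
        R = {i: math.fsum(D[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                # grouped so the result is identical whichever of i, j
                # comes first in the active list (leaf-order invariance)
                q = (r - 2) * D[i, j] - (R[i] + R[j])
                lab = tuple(sorted((minlab[i], minlab[j])))
                key = (q, lab)
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (R[i] - R[j]) / (2 * (r - 2))
        lj = D[i, j] - li
        if li < 0:
            clamped += 1
            li = 0.0
        if lj < 0:
            clamped += 1
            lj = 0.0
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        # grow matrix with the new cluster
        D = np.pad(D, ((0, 1), (0, 1)))
        u = D.shape[0] - 1
        for k in active:
            if k in (i, j):
                continue
            D[u, k] = D[k, u] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        nodes.append(new)
        minlab.append(min(minlab[i], minlab[j]))
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    lengths = []
    for l in (li, lj, lk):
        if l < 0:
            clamped += 1
            l = 0.0
        lengths.append(l)
    root = TreeNode(children=[(nodes[i], lengths[0]), (nodes[j], lengths[1]),
                              (nodes[k], lengths[2])])
    return PhyloTree(root, list(dm.labels), clamped)


def bootstrap_support(
    column_strings: list,
    labels: list,
    n_reps: int = 500,
    seed: int = 0,
    min_overlap: int = MIN_OVERLAP,
) -> PhyloTree:
    """NJ tree with column-resampling bootstrap supports.

    Support of a bipartition of the full-data tree is the fraction of
    replicate trees containing it.  Replicates whose resampled matrix has a
    pair with insufficient overlap are dropped and counted; more than 20 %
    dropped is an error.  Zero-length internal edges (indistinguishable
    sequences) are assigned support 1.0 by policy.
    """
    if n_reps < 1:
        raise InputError("n_reps must be >= 1")
    full_dm = p_distance_matrix(column_strings, labels, min_overlap)
    tree = nj_tree(full_dm)
    target = {}
    for node, split in tree._edges_below():
        full = frozenset(labels)
        key = min(split, full - split, key=lambda s: (len(s), sorted(s)))
        target[id(node)] = (node, key)

    L = len(column_strings[0])
    rng = np.random.default_rng(seed)
    counts = {key: 0 for _, key in target.values()}
    dropped = 0
    done = 0
    for _ in range(n_reps):
        idx = rng.integers(0, L, size=L)
        resampled = ["".join(s[i] for i in idx) for s in column_strings]
        try:
            rep_tree = nj_tree(p_distance_matrix(resampled, labels, min_overlap))
        except InputError:
            dropped += 1
            continue
        done += 1
        rep_splits = rep_tree.splits()
        for key in counts:
            if key in rep_splits:
                counts[key] += 1
    if dropped > 0.2 * n_reps:
        raise InputError(f"too many dropped bootstrap replicates ({dropped}/{n_reps})")
    supports = {}
    for node, key in target.values():
        frac = counts[key] / done if done else 0.0
        node.support = frac
        supports[key] = frac
    # zero-length trivial splits policy
    def fix_zero(node: TreeNode) -> None:
        for child, bl in node.children:
            if not child.is_leaf() and bl == 0.0 and child.support is not None:
                lv = frozenset(child.leaves())
                full = frozenset(labels)
                key = min(lv, full - lv, key=lambda s: (len(s), sorted(s)))
                if supports.get(key, 0.0) == 0.0:
                    child.support = 1.0
                    supports[key] = 1.0
            fix_zero(child)

    fix_zero(tree.root)
    tree.supports = supports
    return tree


def phylip_matrix(dm: DistanceMatrix) -> str:
    """PHYLIP square-format serialization of a distance matrix."""
    lines = [f" {len(dm.labels)}"]
    for lab, row in zip(dm.labels, dm.values):
        name = f"{lab[:10]:<10}"
        lines.append(name + " ".join(f"{v:.6f}" for v in row))
    return "\n".join(lines) + "\n"
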