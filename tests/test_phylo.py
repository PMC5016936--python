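import itertools

import numpy as np
import pytest

from ervkit.errors import InputError
from ervkit.phylo import (
    DistanceMatrix,
    bootstrap_support,
    nj_tree,
    p_distance_matrix,
    phylip_matrix,
)
from ervkit.simulate import mutate_sequence


def random_additive_matrix(rng, n):
    """Random binary tree with positive branch lengths -> additive matrix.

    Returns (labels, matrix, splits) where splits are the tree's non-trivial
    bipartitions (oracle for NJ consistency).
    """
    labels = [f"t{i}" for i in range(n)]
    nodes = [(frozenset([lab]),) for lab in labels]
    children: dict = {}
    lengths: dict = {}
    items = [frozenset([lab]) for lab in labels]
    for leaf in items:
        lengths[leaf] = float(rng.uniform(0.5, 3.0))
    while len(items) > 2:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        a, b = items[j], items[i]
        merged = a | b
        children[merged] = (a, b)
        lengths[merged] = float(rng.uniform(0.5, 3.0))
        items = [x for k, x in enumerate(items) if k not in (i, j)] + [merged]
    root_kids = list(items)

    def leaf_depths(cluster, acc, out):
        if cluster in children:
            a, b = children[cluster]
            leaf_depths(a, acc + lengths[a], out)
            leaf_depths(b, acc + lengths[b], out)
        else:
            out[next(iter(cluster))] = acc

    depths_per_side = []
    for kid in root_kids:
        out: dict = {}
        leaf_depths(kid, lengths[kid], out)
        depths_per_side.append(out)

    idx = {lab: k for k, lab in enumerate(labels)}
    D = np.zeros((n, n))

    def dist(la, lb):
        for side in depths_per_side:
            if la in side and lb in side:
                # walk down to the lowest common cluster
                def path(cluster, leaf, acc):
                    if cluster not in children:
                        return acc if next(iter(cluster)) == leaf else None
                    a, b = children[cluster]
                    pa = path(a, leaf, acc + [a])
                    return pa if pa is not None else path(b, leaf, acc + [b])

                for kid in root_kids:
                    if la in _leaves(kid, children) and lb in _leaves(kid, children):
                        pa = path(kid, la, [kid])
                        pb = path(kid, lb, [kid])
                        shared = 0
                        for x, y in zip(pa, pb):
                            if x == y:
                                shared += 1
                            else:
                                break
                        da = sum(lengths[c] for c in pa[shared:])
                        db = sum(lengths[c] for c in pb[shared:])
                        return da + db
        # opposite sides of the root edge
        return depths_per_side[0].get(la, depths_per_side[1].get(la)) + \
            depths_per_side[0].get(lb, depths_per_side[1].get(lb))

    for la, lb in itertools.combinations(labels, 2):
        d = dist(la, lb)
        D[idx[la], idx[lb]] = D[idx[lb], idx[la]] = d

    full = frozenset(labels)
    splits = set()
    for cluster in children:
        if 2 <= len(cluster) <= n - 2:
            other = full - cluster
            splits.add(min(cluster, other, key=lambda s: (len(s), sorted(s))))
    for kid in root_kids:
        lv = _leaves(kid, children)
        if 2 <= len(lv) <= n - 2:
            other = full - lv
            splits.add(min(lv, other, key=lambda s: (len(s), sorted(s))))
    return labels, D, splits


def _leaves(cluster, children):
    if cluster not in children:
        return cluster
    a, b = children[cluster]
    return _leaves(a, children) | _leaves(b, children)


class TestPDistance:
    def test_identical_sequences(self):
        dm = p_distance_matrix(["ACGT" * 20] * 3, ["a", "b", "c"])
        assert np.all(dm.values == 0)

    def test_five_of_hundred(self):
        a = "ACGT" * 25
        b = list(a)
        for i in range(5):
            b[i * 7] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[i * 7]]
        dm = p_distance_matrix([a, "".join(b), a], ["x", "y", "z"])
        assert dm.values[0, 1] == pytest.approx(0.05)

    def test_disjoint_coverage_error(self):
        a = "ACGT" * 20 + "-" * 80
        b = "-" * 80 + "ACGT" * 20
        c = "ACGT" * 40
        with pytest.raises(InputError, match="insufficient overlap.*x.*y"):
            p_distance_matrix([a, b, c], ["x", "y", "z"])

    def test_pairwise_deletion(self):
        a = "AAAA" * 10 + "-" * 20
        b = "AAAA" * 10 + "C" * 20
        c = "AAAA" * 10 + "C" * 20
        dm = p_distance_matrix([a, b, c], ["x", "y", "z"])
        assert dm.values[0, 1] == 0.0  # gaps deleted pairwise
        assert dm.values[1, 2] == 0.0


class TestNJ:
    def test_three_taxa_closed_form(self):
        D = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        tree = nj_tree(DistanceMatrix(["a", "b", "c"], D))
        lengths = {c.name: bl for c, bl in tree.root.children}
        assert lengths["a"] == pytest.approx((5 + 9 - 10) / 2)
        assert lengths["b"] == pytest.approx((5 + 10 - 9) / 2)
        assert lengths["c"] == pytest.approx((9 + 10 - 5) / 2)

    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):3,C:4,D:5): the only non-trivial split is {A,B}
        D = np.array(
            [[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]], float
        )
        tree = nj_tree(DistanceMatrix(list("ABCD"), D))
        assert tree.splits() == {frozenset("AB")}
        assert tree.negative_branches_clamped == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_six_taxon_additive_consistency(self, seed):
        rng = np.random.default_rng(seed)
        labels, D, expected_splits = random_additive_matrix(rng, 6)
        tree = nj_tree(DistanceMatrix(labels, D))
        assert tree.splits() == expected_splits

    @pytest.mark.parametrize("seed", range(4))
    def test_additive_branch_lengths_recovered(self, seed):
        # NJ on an additive matrix reproduces the matrix itself
        rng = np.random.default_rng(100 + seed)
        labels, D, _ = random_additive_matrix(rng, 6)
        tree = nj_tree(DistanceMatrix(labels, D))

        def tree_distances(node, acc, out):
            if node.is_leaf():
                out[node.name] = acc
                return
            for child, bl in node.children:
                tree_distances(child, acc + bl, out)

        # distance between leaves via the (arbitrary) root is additive
        per_leaf: dict = {}
        tree_distances(tree.root, 0.0, per_leaf)
        # verify pairwise path lengths against D using root paths:
        # d(x,y) = depth(x) + depth(y) - 2 * depth(lca); instead check the
        # four-point condition holds by re-deriving distances recursively
        def pairwise(node):
            if node.is_leaf():
                return {node.name: 0.0}, {}
            depths: dict = {}
            dists: dict = {}
            sides = []
            for child, bl in node.children:
                d_child, dist_child = pairwise(child)
                d_child = {k: v + bl for k, v in d_child.items()}
                dists.update(dist_child)
                sides.append(d_child)
                depths.update(d_child)
            for i in range(len(sides)):
                for j in range(i + 1, len(sides)):
                    for x, dx in sides[i].items():
                        for y, dy in sides[j].items():
                            dists[frozenset((x, y))] = dx + dy
            return depths, dists

        _, dists = pairwise(tree.root)
        idx = {lab: k for k, lab in enumerate(labels)}
        for pair, dval in dists.items():
            x, y = tuple(pair)
            assert dval == pytest.approx(D[idx[x], idx[y]], abs=1e-9)

    def test_non_symmetric_rejected(self):
        D = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]])
        with pytest.raises(InputError, match="symmetric"):
            DistanceMatrix(["a", "b", "c"], D)

    def test_subgroup_clusters_separate(self, model):
        base = model.sequence[:780]
        far = mutate_sequence(base, 0.08, seed=1)
        cols = [mutate_sequence(base, 0.01, seed=10 + i) for i in range(3)]
        cols += [mutate_sequence(far, 0.01, seed=20 + i) for i in range(3)]
        labels = ["a1", "a2", "a3", "b1", "b2", "b3"]
        tree = nj_tree(p_distance_matrix(cols, labels))
        assert frozenset(["a1", "a2", "a3"]) in tree.splits()


class TestBootstrap:
    def _clades(self, model, between=0.08, within=0.01, n=4):
        base = model.sequence[:780]
        far = mutate_sequence(base, between, seed=99)
        cols = [mutate_sequence(base, within, seed=i) for i in range(n)]
        cols += [mutate_sequence(far, within, seed=50 + i) for i in range(n)]
        labels = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]
        return cols, labels

    def test_separated_clades_high_support(self, model):
        cols, labels = self._clades(model)
        tree = bootstrap_support(cols, labels, n_reps=100, seed=3)
        split = frozenset(labels[:4])
        assert tree.supports[split] >= 0.95

    def test_deterministic(self, model):
        cols, labels = self._clades(model, n=3)
        t1 = bootstrap_support(cols, labels, n_reps=1, seed=11)
        t2 = bootstrap_support(cols, labels, n_reps=1, seed=11)
        assert t1.supports == t2.supports

    def test_identical_sequences_policy(self, model):
        cols = [model.sequence[:300]] * 5
        labels = list("abcde")
        tree = bootstrap_support(cols, labels, n_reps=10, seed=2)
        for split, sup in tree.supports.items():
            assert sup == 1.0  # zero-length trivial splits policy

    def test_leaf_order_invariance(self, model):
        cols, labels = self._clades(model, n=3)
        t1 = bootstrap_support(cols, labels, n_reps=50, seed=7)
        order = [4, 2, 0, 5, 1, 3]
        t2 = bootstrap_support([cols[i] for i in order],
                               [labels[i] for i in order], n_reps=50, seed=7)
        assert t1.supports == t2.supports

    def test_invalid_reps(self, model):
        cols, labels = self._clades(model, n=3)
        with pytest.raises(InputError):
            bootstrap_support(cols, labels, n_reps=0)


def test_phylip_serialization():
    dm = DistanceMatrix(["a", "b", "c"],
                        np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float))
    text = phylip_matrix(dm)
    lines = text.strip().split("\n")
    assert lines[0].strip() == "3"
    assert lines[1].startswith("a")
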