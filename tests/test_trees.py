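"""Neighbor joining, bootstrap supports, and the nesting test."""

import numpy as np
import pytest

from nlrforge.trees import (
    Tree,
    TreeNode,
    bootstrap_support,
    cluster_nesting,
    neighbor_joining,
    p_distance_matrix,
)


def random_additive_tree(labels, rng):
    """Random rooted binary tree with positive branch lengths + leaf distances."""

    def build(labs):
        if len(labs) == 1:
            return TreeNode(name=labs[0], length=float(rng.uniform(0.1, 1.0)))
        k = int(rng.integers(1, len(labs)))
        node = TreeNode(length=float(rng.uniform(0.1, 1.0)))
        node.children = [build(labs[:k]), build(labs[k:])]
        return node

    labs = list(labels)
    rng.shuffle(labs)
    root = TreeNode(children=[build(labs[:1]), build(labs[1:])])
    tree = Tree(root)

    # path-length distances between leaves
    paths = {}

    def walk(node, acc):
        acc = acc + [node]
        if node.is_leaf():
            paths[node.name] = acc
        for c in node.children:
            walk(c, acc)

    walk(root, [])
    n = len(labels)
    d = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                pa, pb = paths[a], paths[b]
                common = 0
                for x, y in zip(pa, pb):
                    if x is y:
                        common += 1
                    else:
                        break
                dist = sum(nd.length for nd in pa[common:]) + sum(
                    nd.length for nd in pb[common:]
                )
                d[i, j] = d[j, i] = dist
    return tree, d


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = np.array([[0.0, 2.0, 4.0], [2.0, 0.0, 4.0], [4.0, 4.0, 0.0]])
        tree = neighbor_joining(d, ["a", "b", "c"])
        lengths = {n.name: n.length for n in tree.root.children}
        assert lengths == {"a": 1.0, "b": 1.0, "c": 3.0}

    def test_fewer_than_three_taxa_is_error(self):
        with pytest.raises(ValueError):
            neighbor_joining(np.zeros((2, 2)), ["a", "b"])

    def test_nan_distance_is_error(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValueError):
            neighbor_joining(d, list("abc"))

    def test_recovers_additive_five_leaf_topology(self):
        rng = np.random.default_rng(4)
        labels = list("abcde")
        for _ in range(20):
            true_tree, d = random_additive_tree(labels, rng)
            nj = neighbor_joining(d, labels)
            assert nj.bipartitions() == true_tree.bipartitions()

    def test_all_equal_distances_deterministic(self):
        d = np.ones((5, 5)) - np.eye(5)
        t1 = neighbor_joining(d, list("abcde")).to_newick()
        t2 = neighbor_joining(d, list("abcde")).to_newick()
        assert t1 == t2

    def test_branch_lengths_nonnegative_after_clamping(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = 6
            d = np.abs(rng.normal(1.0, 0.5, (n, n)))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            tree = neighbor_joining(d, [f"t{i}" for i in range(n)])

            def check(node):
                assert node.length >= 0.0
                for c in node.children:
                    check(c)

            for c in tree.root.children:
                check(c)

    def test_agrees_with_skbio_on_additive_matrices(self):
        """Independent cross-check against scikit-bio's NJ implementation."""
        import io as _io

        from skbio import DistanceMatrix, TreeNode as SkbioNode
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(21)
        labels = [f"t{i}" for i in range(6)]
        for _ in range(10):
            _true, d = random_additive_tree(labels, rng)
            ours = neighbor_joining(d, labels)
            theirs = skbio_nj(DistanceMatrix(d, labels))
            ours_sk = SkbioNode.read(_io.StringIO(ours.to_newick()))
            rf = ours_sk.compare_rfd(theirs)
            assert rf == 0.0


class TestNewick:
    def test_round_trip_preserves_topology(self):
        rng = np.random.default_rng(13)
        labels = list("abcdefg")
        _t, d = random_additive_tree(labels, rng)
        tree = neighbor_joining(d, labels)
        back = Tree.from_newick(tree.to_newick())
        assert back.bipartitions() == tree.bipartitions()
        assert sorted(back.leaf_names()) == sorted(labels)


class TestBootstrap:
    def _msa(self, seqs):
        return dict(seqs)

    def test_seed_determinism(self):
        rng = np.random.default_rng(1)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        base = "".join(aa[i] for i in rng.integers(0, 20, 60))
        msa = {f"t{i}": base for i in range(4)}
        t1 = bootstrap_support(msa, n_reps=25, seed=7)
        t2 = bootstrap_support(msa, n_reps=25, seed=7)
        assert t1.to_newick() == t2.to_newick()

    def test_too_few_columns_is_error(self):
        with pytest.raises(ValueError):
            bootstrap_support({"a": "M", "b": "M", "c": "M"}, seed=0)

    def test_separated_clades_get_high_support(self):
        """Two 3-leaf clades at 40% between / ~1% within divergence."""
        rng = np.random.default_rng(2)
        aa = "ACDEFGHIKLMNPQRSTVWY"

        def mutate(seq, rate):
            out = list(seq)
            for i in range(len(out)):
                if rng.random() < rate:
                    out[i] = aa[int(rng.integers(0, 20))]
            return "".join(out)

        anc = "".join(aa[i] for i in rng.integers(0, 20, 300))
        clade_a = mutate(anc, 0.4)
        msa = {f"a{i}": mutate(anc, 0.01) for i in range(3)}
        msa.update({f"b{i}": mutate(clade_a, 0.01) for i in range(3)})
        tree = bootstrap_support(msa, n_reps=100, seed=3)
        split = frozenset(["a0", "a1", "a2"])
        complement = frozenset(msa) - split
        best = 0.0
        for node in tree.internal_edges():
            side = frozenset(leaf.name for leaf in node.leaves())
            if side in (split, complement):
                best = max(best, node.support or 0.0)
        assert best >= 0.95


class TestClusterNesting:
    def _tree(self):
        # ((a,b),(c,d),e); — cherry (a,b) and cherry (c,d)
        return Tree.from_newick("((a:1,b:1):1,(c:1,d:1):1,e:1);")

    def test_cherry_pair_nests(self):
        assert cluster_nesting(self._tree(), ["a", "b"])

    def test_split_pair_does_not_nest(self):
        assert not cluster_nesting(self._tree(), ["a", "c"])

    def test_single_member_trivially_nests(self):
        assert cluster_nesting(self._tree(), ["e"])

    def test_missing_member_is_error(self):
        with pytest.raises(ValueError, match="missing"):
            cluster_nesting(self._tree(), ["a", "zzz"])

    def test_planted_tandem_clusters_nest_distant_mixtures_do_not(self, small_parsed):
        """NJ over two planted families: each family nests, a mixture does not."""
        truth = small_parsed["truth"]
        fams = [
            ms for ms in truth["clusters"].values() if len(ms) >= 2
        ]
        assert len(fams) >= 2
        fam_a, fam_b = fams[0][:2], fams[1][:2]
        seqs = {}
        for gid in fam_a + fam_b:
            pid = gid + ".1"
            seqs[gid] = small_parsed["proteins_by_id"][pid].sequence
        from nlrforge.align import progressive_align

        msa = progressive_align(seqs)
        tree = neighbor_joining(
            p_distance_matrix([msa[g] for g in fam_a + fam_b]), fam_a + fam_b
        )
        assert cluster_nesting(tree, fam_a)
        assert cluster_nesting(tree, fam_b)
        assert not cluster_nesting(tree, [fam_a[0], fam_b[0]])
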