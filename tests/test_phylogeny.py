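import numpy as np
import pytest

from gpcrsel.codon_alignment import ProteinAlignment
from gpcrsel.phylogeny import (
    PhylogenyError,
    Tree,
    bootstrap_consensus,
    jtt_ml_distance,
    jtt_model,
    kimura_distance,
    neighbor_joining,
    protein_distance_matrix,
)

AAS = list("ACDEFGHIKLMNPQRSTVWY")


def leaf_distances(tree: Tree) -> dict[frozenset, float]:
    """Leaf-pair path lengths keyed by label pairs (label-order independent)."""
    parent = {}
    for n in tree.postorder():
        for c in n.children:
            parent[id(c)] = n
    leaves = tree.leaves()

    def ancestors(n):
        d, acc = {}, 0.0
        while id(n) in parent:
            acc += n.length
            n = parent[id(n)]
            d[id(n)] = acc
        return d

    out = {}
    for i, a in enumerate(leaves):
        da = ancestors(a)
        for b in leaves[i + 1 :]:
            db = ancestors(b)
            common = set(da) & set(db)
            lca = min(common, key=lambda k: da[k])
            out[frozenset({a.name, b.name})] = da[lca] + db[lca]
    return out


def random_additive_tree(n, rng):
    """Random binary tree with positive branch lengths and its metric."""
    nodes = [Tree.from_newick(f"({chr(97 + i)}:0.0);").root.children[0] for i in range(n)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        from gpcrsel.phylogeny import Node

        a, b = nodes[j], nodes[i]
        a.length = float(rng.uniform(0.2, 2.0))
        b.length = float(rng.uniform(0.2, 2.0))
        parent = Node(children=[b, a])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [parent]
    from gpcrsel.phylogeny import Node

    for nd in nodes:
        nd.length = float(rng.uniform(0.2, 2.0))
    tree = Tree(Node(children=nodes))
    return tree


class TestNeighborJoining:
    def test_three_taxa_solved_exactly(self):
        D = np.array([[0, 5, 8], [5, 0, 9], [8, 9, 0]], float)
        tree = neighbor_joining(D, ["a", "b", "c"])
        lengths = {c.name: c.length for c in tree.root.children}
        assert lengths == {"a": 2.0, "b": 3.0, "c": 6.0}

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_additive_matrices_recovered_exactly(self, seed):
        rng = np.random.default_rng(seed)
        true = random_additive_tree(6, rng)
        truth = leaf_distances(true)
        labels = true.leaf_names()
        D = np.zeros((6, 6))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    D[i, j] = D[j, i] = truth[frozenset({a, b})]
        rec = neighbor_joining(D, labels)
        got = leaf_distances(rec)
        assert rec.bipartitions() == true.bipartitions()
        for pair, d in truth.items():
            assert got[pair] == pytest.approx(d, abs=1e-9)

    def test_matches_independent_nj_implementation(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(7)
        true = random_additive_tree(7, rng)
        labels = true.leaf_names()
        truth = leaf_distances(true)
        D = np.zeros((7, 7))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    D[i, j] = D[j, i] = truth[frozenset({a, b})]
        ours = neighbor_joining(D, labels)
        theirs = Tree.from_newick(str(skbio_nj(DistanceMatrix(D, ids=labels))))
        assert ours.bipartitions() == theirs.bipartitions()

    def test_ultrametric_equal_distances_give_zero_internal_branches(self):
        D = np.full((4, 4), 2.0)
        np.fill_diagonal(D, 0.0)
        tree = neighbor_joining(D, list("abcd"))
        internal = [n for n in tree.edges() if not n.is_leaf]
        assert all(n.length == pytest.approx(0.0, abs=1e-12) for n in internal)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(PhylogenyError):
            neighbor_joining(np.array([[0, 1], [1, 0]], float), ["a", "b"])
        bad = np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]], float)
        with pytest.raises(PhylogenyError):
            neighbor_joining(bad, list("abc"))
        nan = np.zeros((3, 3))
        nan[0, 1] = nan[1, 0] = np.nan
        with pytest.raises(PhylogenyError):
            neighbor_joining(nan, list("abc"))


class TestProteinDistances:
    def test_identical_sequences_have_zero_distance(self):
        row = np.array(list("ACDEFGHIKL"))
        assert jtt_ml_distance(row, row) == 0.0
        assert kimura_distance(row, row) == 0.0

    def test_kimura_closed_form_one_difference_in_hundred(self):
        a = np.array(list("A" * 99 + "C"))
        b = np.array(list("A" * 99 + "D"))
        expected = -np.log(1 - 0.01 - 0.2 * 0.01**2)
        assert kimura_distance(a, b) == pytest.approx(expected, rel=1e-12)

    def test_jtt_distance_monotone_in_observed_differences(self, rng):
        base = rng.choice(AAS, size=200)
        prev = 0.0
        for k in (2, 8, 20, 50, 90):
            other = base.copy()
            for idx in range(k):
                choices = [a for a in AAS if a != base[idx]]
                other[idx] = choices[int(rng.integers(len(choices)))]
            d = jtt_ml_distance(base, other)
            assert d > prev
            prev = d

    def test_jtt_generator_is_proper_and_scaled(self):
        m = jtt_model()
        Q, pi = m["Q"], m["pi"]
        assert np.abs(Q.sum(axis=1)).max() < 1e-12
        assert -np.sum(pi * np.diag(Q)) == pytest.approx(1.0)
        assert pi @ Q == pytest.approx(np.zeros(20), abs=1e-12)

    def test_pairwise_deletion_requires_shared_columns(self):
        aln = ProteinAlignment(["a", "b"], np.array([["A", "-"], ["-", "C"]]))
        with pytest.raises(PhylogenyError):
            protein_distance_matrix(aln, model="JTT-ML")


class TestNewick:
    def test_round_trip_preserves_topology_lengths_and_support(self):
        nw = "((a:0.123456789,b:0.2)75:0.05,(c:0.3,d:0.4)90:0.06,e:0.5);"
        tree = Tree.from_newick(nw)
        back = Tree.from_newick(tree.to_newick(include_support=True))
        assert back.bipartitions() == tree.bipartitions()
        d1, d2 = leaf_distances(tree), leaf_distances(back)
        for pair in d1:
            assert d2[pair] == pytest.approx(d1[pair], abs=1e-9)
        supports = sorted(
            n.support for n in back.postorder() if n.support is not None
        )
        assert supports == [75.0, 90.0]


class TestBootstrap:
    def _signal_alignment(self):
        rng = np.random.default_rng(0)
        base = rng.choice(AAS, size=(1, 80))
        res = np.vstack([base] * 5).astype("<U1")
        for idx in range(0, 40, 2):
            res[0, idx] = res[1, idx] = "W"
        for idx in range(1, 40, 2):
            res[2, idx] = res[3, idx] = "C"
        return ProteinAlignment([f"s{i}" for i in range(1, 6)], res)

    def test_single_replicate_gives_full_support(self):
        aln = self._signal_alignment()
        cons = bootstrap_consensus(aln, n_reps=1, seed=3, model="kimura")
        supports = [n.support for n in cons.postorder() if n.support is not None]
        assert supports and all(s == pytest.approx(100.0) for s in supports)

    def test_clean_signal_recovers_true_bipartitions_with_high_support(self):
        aln = self._signal_alignment()
        cons = bootstrap_consensus(aln, n_reps=100, seed=3, model="kimura")
        bips = cons.bipartitions()
        assert frozenset({"s1", "s2"}) in bips or frozenset({"s3", "s4", "s5"}) in bips
        assert frozenset({"s3", "s4"}) in bips or frozenset({"s1", "s2", "s5"}) in bips
        supports = [n.support for n in cons.postorder() if n.support is not None]
        assert min(supports) > 50.0

    def test_seed_is_required_and_deterministic(self):
        aln = self._signal_alignment()
        with pytest.raises(PhylogenyError):
            bootstrap_consensus(aln, n_reps=5, seed=None)
        t1 = bootstrap_consensus(aln, n_reps=10, seed=11, model="kimura")
        t2 = bootstrap_consensus(aln, n_reps=10, seed=11, model="kimura")
        assert t1.to_newick(include_support=True) == t2.to_newick(include_support=True)
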