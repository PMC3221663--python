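"""Protein distance matrices, neighbor joining, and bootstrap consensus.

Distances use either the JTT amino-acid replacement model (per-pair maximum
likelihood of divergence time under the standard JTT rate matrix) or the
Kimura correction d = -ln(1 - p - p^2/5). Trees are built with the
Saitou-Nei neighbor-joining agglomeration; negative branch-length estimates
are clamped to zero with the deficit shifted to the sister branch. Newick
serialization is handled via dendropy, and majority-rule bootstrap consensus
via Biopython's consensus machinery.
"""
from __future__ import annotations

import importlib.resources
import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio import Phylo
from Bio.Phylo import Consensus as _Consensus
from scipy.optimize import minimize_scalar

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}


class PhylogenyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# tree structure


@dataclass
class Node:
    name: str | None = None
    length: float = 0.0  # branch to parent
    support: float | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Tree:
    """Rooted representation of an (optionally unrooted) phylogeny.

    Unrooted NJ trees are stored with the conventional trifurcation at the
    root; all other internal nodes are binary.
    """

    def __init__(self, root: Node):
        self.root = root

    def postorder(self) -> list[Node]:
        out: list[Node] = []

        def visit(node: Node) -> None:
            for ch in node.children:
                visit(ch)
            out.append(node)

        visit(self.root)
        return out

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def edges(self) -> list[Node]:
        """All nodes except the root; each carries its branch to the parent."""
        return [n for n in self.postorder() if n is not self.root]

    def total_length(self) -> float:
        return sum(n.length for n in self.edges())

    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            return Node(
                node.name, node.length, node.support, [clone(c) for c in node.children]
            )

        return Tree(clone(self.root))

    def bipartitions(self) -> set[frozenset[str]]:
        """Leaf-set bipartitions induced by internal edges (smaller side,
        normalized as the side not containing the first leaf)."""
        all_leaves = frozenset(self.leaf_names())
        first = min(all_leaves)
        out: set[frozenset[str]] = set()

        def below(node: Node) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])
            acc: set[str] = set()
            for ch in node.children:
                acc |= below(ch)
            return frozenset(acc)

        for node in self.edges():
            if node.is_leaf:
                continue
            side = below(node)
            if first in side:
                side = all_leaves - side
            if 1 < len(side) < len(all_leaves) - 1:
                out.add(side)
        return out

    def to_newick(self, include_support: bool = False) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.9f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if include_support and node.support is not None:
                label = f"{node.support:g}"
            return f"({inner}){label}:{node.length:.9f}"

        inner = ",".join(fmt(c) for c in self.root.children)
        label = ""
        if include_support and self.root.support is not None:
            label = f"{self.root.support:g}"
        return f"({inner}){label};"

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        dtree = dendropy.Tree.get(data=newick, schema="newick")

        def convert(dnode) -> Node:
            node = Node(
                name=dnode.taxon.label.replace(" ", "_") if dnode.taxon else None,
                length=dnode.edge.length or 0.0,
            )
            if dnode.label is not None:
                try:
                    node.support = float(dnode.label)
                except ValueError:
                    pass
            node.children = [convert(c) for c in dnode.child_nodes()]
            return node

        return cls(convert(dtree.seed_node))


def write_newick(tree: Tree, path, include_support: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick(include_support=include_support) + "\n")


def read_newick(path) -> Tree:
    with open(path) as fh:
        return Tree.from_newick(fh.read())


# ---------------------------------------------------------------------------
# JTT model and protein distances

_JTT_CACHE: dict | None = None


def jtt_model() -> dict:
    """JTT rate matrix pieces: frequencies, eigendecomposition of the
    reversible generator scaled to one expected replacement per unit time."""
    global _JTT_CACHE
    if _JTT_CACHE is None:
        path = importlib.resources.files("gpcrsel").joinpath("data/jtt.tsv")
        rows = []
        freqs = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or line.startswith("aa\t"):
                    continue
                parts = line.rstrip("\n").split("\t")
                rows.append([float(x) for x in parts[1:21]])
                freqs.append(float(parts[21]))
        S = np.array(rows)
        pi = np.array(freqs)
        pi = pi / pi.sum()
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -np.sum(pi * np.diag(Q))
        Q /= mu
        # reversible: symmetrize and eigendecompose
        d = np.sqrt(pi)
        sym = (Q * d[:, None]) / d[None, :]
        sym = 0.5 * (sym + sym.T)
        eigval, eigvec = np.linalg.eigh(sym)
        _JTT_CACHE = {
            "pi": pi,
            "Q": Q,
            "eigval": eigval,
            "left": eigvec.T * d[None, :],  # maps x -> U^T D^{1/2} x
            "right": eigvec / d[:, None],  # D^{-1/2} U
        }
    return _JTT_CACHE


def jtt_transition_matrix(t: float) -> np.ndarray:
    m = jtt_model()
    return (m["right"] * np.exp(m["eigval"] * t)[None, :]) @ m["left"]


def _pair_states(row_a: np.ndarray, row_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ok = np.array(
        [
            (a in _AA_INDEX) and (b in _AA_INDEX)
            for a, b in zip(row_a, row_b)
        ]
    )
    if not ok.any():
        raise PhylogenyError("no shared ungapped columns for a sequence pair")
    xa = np.array([_AA_INDEX[a] for a in row_a[ok]])
    xb = np.array([_AA_INDEX[b] for b in row_b[ok]])
    return xa, xb


def jtt_ml_distance(row_a: np.ndarray, row_b: np.ndarray, t_max: float = 20.0) -> float:
    """ML divergence time of a sequence pair under the JTT model."""
    xa, xb = _pair_states(row_a, row_b)
    if np.all(xa == xb):
        return 0.0
    m = jtt_model()
    log_pi = np.log(m["pi"])

    def neg_loglik(t: float) -> float:
        P = jtt_transition_matrix(t)
        return -float(np.sum(log_pi[xa] + np.log(np.maximum(P[xa, xb], 1e-300))))

    res = minimize_scalar(neg_loglik, bounds=(1e-6, t_max), method="bounded",
                          options={"xatol": 1e-8})
    return float(res.x)


def kimura_distance(row_a: np.ndarray, row_b: np.ndarray) -> float:
    """Kimura-corrected protein distance d = -ln(1 - p - 0.2 p^2)."""
    xa, xb = _pair_states(row_a, row_b)
    p = float(np.mean(xa != xb))
    arg = 1.0 - p - 0.2 * p * p
    if arg <= 0:
        return np.inf
    return -float(np.log(arg))


def protein_distance_matrix(aa_alignment, model: str = "JTT-ML") -> np.ndarray:
    """Symmetric pairwise distance matrix over an amino-acid alignment."""
    if aa_alignment.n_sequences < 2:
        raise PhylogenyError("need at least 2 sequences")
    fn = {"JTT-ML": jtt_ml_distance, "kimura": kimura_distance}.get(model)
    if fn is None:
        raise PhylogenyError(f"unknown distance model {model!r}")
    S = aa_alignment.n_sequences
    D = np.zeros((S, S))
    for i in range(S):
        for j in range(i + 1, S):
            d = fn(aa_alignment.residues[i], aa_alignment.residues[j])
            D[i, j] = D[j, i] = d
    return D


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(D: np.ndarray, labels: list[str]) -> Tree:
    """Saitou-Nei neighbor joining.

    Produces the conventional unrooted tree (trifurcating root). Negative
    branch-length estimates are clamped to zero and the deficit moved to the
    sister branch, preserving the path length between the joined leaves. On
    an additive matrix the generating topology and branch lengths are
    recovered exactly.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or n != len(labels):
        raise PhylogenyError("distance matrix / label size mismatch")
    if n < 3:
        raise PhylogenyError("need at least 3 taxa")
    if not np.allclose(D, D.T, atol=1e-9) or np.any(np.diag(D) != 0):
        raise PhylogenyError("matrix must be symmetric with zero diagonal")
    if np.any(~np.isfinite(D)):
        raise PhylogenyError("non-finite distances")

    nodes: list[Node] = [Node(name=l) for l in labels]
    dist = D.copy()
    active = list(range(n))

    def clamp_pair(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = dist[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_, j_ = np.unravel_index(np.argmin(q), q.shape)
        if i_ > j_:
            i_, j_ = j_, i_
        ai, aj = active[i_], active[j_]
        dij = sub[i_, j_]
        li = 0.5 * dij + (r[i_] - r[j_]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = clamp_pair(li, lj)
        parent = Node()
        child_i, child_j = nodes[ai], nodes[aj]
        child_i.length = li
        child_j.length = lj
        parent.children = [child_i, child_j]
        # distances from the new node
        new_d = 0.5 * (dist[ai, :] + dist[aj, :] - dij)
        dist = np.vstack([dist, new_d])
        new_col = np.append(new_d, 0.0)
        dist = np.column_stack([dist, new_col])
        nodes.append(parent)
        active = [a for a in active if a not in (ai, aj)] + [len(nodes) - 1]

    # resolve the final three branches around the root trifurcation
    a, b, c = active
    la = 0.5 * (dist[a, b] + dist[a, c] - dist[b, c])
    lb = 0.5 * (dist[a, b] + dist[b, c] - dist[a, c])
    lc = 0.5 * (dist[a, c] + dist[b, c] - dist[a, b])
    lens = [la, lb, lc]
    for k in range(3):
        if lens[k] < 0:
            # move the deficit to the longer of the two sisters
            other = max(range(3), key=lambda x: lens[x])
            lens[other] += lens[k]
            lens[k] = 0.0
    root = Node()
    for idx, l in zip((a, b, c), lens):
        nodes[idx].length = max(l, 0.0)
        root.children.append(nodes[idx])
    return Tree(root)


def nj_tree(aa_alignment, model: str = "JTT-ML") -> Tree:
    """Distance matrix + NJ in one step."""
    D = protein_distance_matrix(aa_alignment, model=model)
    return neighbor_joining(D, list(aa_alignment.labels))


# ---------------------------------------------------------------------------
# bootstrap consensus


def bootstrap_consensus(
    aa_alignment,
    n_reps: int = 100,
    seed: int | None = None,
    model: str = "JTT-ML",
    min_freq: float = 0.5,
) -> Tree:
    """Column-resampling bootstrap with majority-rule consensus.

    Support values are bipartition frequencies in [0, 100]. The random seed
    is an explicit parameter; no global state is consulted.
    """
    if n_reps < 1:
        raise PhylogenyError("n_reps must be >= 1")
    if seed is None:
        raise PhylogenyError("bootstrap requires an explicit seed")
    rng = np.random.default_rng(seed)
    L = aa_alignment.column_count
    from .codon_alignment import ProteinAlignment

    newicks = []
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        resampled = ProteinAlignment(
            list(aa_alignment.labels), aa_alignment.residues[:, cols]
        )
        tree = nj_tree(resampled, model=model)
        newicks.append(tree.to_newick())

    bio_trees = [
        Phylo.read(io.StringIO(nw), "newick") for nw in newicks
    ]
    consensus = _Consensus.majority_consensus(bio_trees, cutoff=min_freq)
    buf = io.StringIO()
    Phylo.write(consensus, buf, "newick")
    tree = Tree.from_newick(buf.getvalue())
    # Biopython writes confidences as internal node labels already parsed
    # into support by Tree.from_newick; rescale to percentages if needed.
    for node in tree.postorder():
        if node.support is not None and node.support <= 1.0:
            node.support *= 100.0
    return tree


def write_phylip_distances(D: np.ndarray, labels: list[str], path) -> None:
    """Lower-triangle PHYLIP distance-matrix dialect."""
    with open(path, "w") as fh:
        fh.write(f"{len(labels)}\n")
        for i, label in enumerate(labels):
            row = " ".join(f"{D[i, j]:.6f}" for j in range(i))
            fh.write(f"{label:<10s} {row}\n".rstrip() + "\n")
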