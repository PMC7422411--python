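"""Neighbor joining, bootstrap support and cluster-nesting tests.

The NJ implementation follows the Saitou–Nei agglomeration with two
declared determinism rules: Q-matrix ties are broken by the smallest
(row, col) index pair, and a negative branch length is clamped to zero
with the deficit moved onto the sister branch.  Trees are unrooted; the
root node is the trifurcation left by the final join.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np


@dataclass
class TreeNode:
    name: Optional[str] = None
    length: float = 0.0
    support: Optional[float] = None
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


class Tree:
    """An unrooted tree represented with an arbitrary internal root."""

    def __init__(self, root: TreeNode, join_order: Optional[list[tuple[str, str]]] = None):
        self.root = root
        self._join_order = join_order or []

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.root.leaves()]

    def join_order(self) -> list[tuple[str, str]]:
        """Leaf-representative pairs in agglomeration order (guide for MSA)."""
        return list(self._join_order)

    # -- bipartitions ------------------------------------------------------
    def bipartitions(self, include_trivial: bool = False) -> set[frozenset[str]]:
        """Canonical splits of the unrooted tree (smaller side, then lexical)."""
        all_leaves = frozenset(self.leaf_names())
        splits: set[frozenset[str]] = set()
        for node, _parent in self._edges():
            side = frozenset(leaf.name for leaf in node.leaves())
            if not include_trivial and (len(side) < 2 or len(all_leaves - side) < 2):
                continue
            splits.add(_canonical(side, all_leaves))
        return splits

    def _edges(self):
        out = []

        def walk(node, parent):
            if parent is not None:
                out.append((node, parent))
            for c in node.children:
                walk(c, node)

        walk(self.root, None)
        return out

    def internal_edges(self) -> list[TreeNode]:
        all_leaves = frozenset(self.leaf_names())
        nodes = []
        for node, _parent in self._edges():
            side = frozenset(leaf.name for leaf in node.leaves())
            if len(side) >= 2 and len(all_leaves - side) >= 2:
                nodes.append(node)
        return nodes

    # -- newick ------------------------------------------------------------
    def to_newick(self) -> str:
        return _newick(self.root, top=True) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        import dendropy

        dt = dendropy.Tree.get(data=text, schema="newick")

        def convert(dnode) -> TreeNode:
            node = TreeNode(
                name=dnode.taxon.label if dnode.taxon else None,
                length=dnode.edge.length or 0.0,
            )
            if dnode.label is not None and not dnode.is_leaf():
                try:
                    node.support = float(dnode.label)
                except ValueError:
                    pass
            node.children = [convert(c) for c in dnode.child_nodes()]
            return node

        return cls(convert(dt.seed_node))


def _canonical(side: frozenset[str], universe: frozenset[str]) -> frozenset[str]:
    other = universe - side
    return min((side, other), key=lambda s: (len(s), sorted(s)))


def _newick(node: TreeNode, top: bool = False) -> str:
    if node.is_leaf():
        return f"{node.name}:{node.length:.6g}"
    inner = ",".join(_newick(c) for c in node.children)
    label = "" if node.support is None else f"{node.support:.6g}"
    if top:
        return f"({inner}){label}"
    return f"({inner}){label}:{node.length:.6g}"


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(distance_matrix: np.ndarray, labels: Sequence[str]) -> Tree:
    """Saitou–Nei neighbor joining on a symmetric distance matrix (n >= 3)."""
    d = np.asarray(distance_matrix, dtype=float).copy()
    n = d.shape[0]
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")

    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in labels]
    reps: list[str] = list(labels)  # representative leaf per active node
    join_order: list[tuple[str, str]] = []

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest (row, col) pair on ties: argmin of the flattened matrix
        # scans row-major, which is exactly that order
        flat = int(np.argmin(q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        ni, nj = nodes[i], nodes[j]
        ni.length, nj.length = li, lj
        parent = TreeNode(children=[ni, nj])
        join_order.append((reps[i], reps[j]))
        du = (d[i, :] + d[j, :] - d[i, j]) / 2
        keep = [k for k in range(m) if k not in (i, j)]
        new_d = np.zeros((m - 1, m - 1))
        new_d[:-1, :-1] = d[np.ix_(keep, keep)]
        new_d[-1, :-1] = new_d[:-1, -1] = du[keep]
        d = new_d
        nodes = [nodes[k] for k in keep] + [parent]
        reps = [reps[k] for k in keep] + [reps[i]]

    # final trifurcation: closed-form branch lengths for three nodes
    la = (d[0, 1] + d[0, 2] - d[1, 2]) / 2
    lb = (d[0, 1] + d[1, 2] - d[0, 2]) / 2
    lc = (d[0, 2] + d[1, 2] - d[0, 1]) / 2
    for node, length in zip(nodes, (la, lb, lc)):
        node.length = max(length, 0.0)
    join_order.append((reps[0], reps[1]))
    join_order.append((reps[0], reps[2]))
    return Tree(TreeNode(children=nodes), join_order=join_order)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def p_distance_matrix(rows: Sequence[str]) -> np.ndarray:
    """Pairwise proportion of differing residues over shared non-gap columns."""
    arr = np.array([list(r) for r in rows])
    n = arr.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (arr[i] != "-") & (arr[j] != "-")
            tot = int(ok.sum())
            d[i, j] = d[j, i] = (
                float((arr[i][ok] != arr[j][ok]).sum()) / tot if tot else 1.0
            )
    return d


def bootstrap_support(
    alignment: Mapping[str, str],
    n_reps: int = 100,
    seed: int = 0,
) -> Tree:
    """NJ tree from an MSA with bootstrap supports on internal edges.

    Columns are resampled with replacement ``n_reps`` times; the support
    of an internal edge is the fraction of replicate trees containing its
    bipartition.
    """
    labels = list(alignment)
    rows = [alignment[lab] for lab in labels]
    n_cols = len(rows[0])
    if n_cols < 2:
        raise ValueError("bootstrap requires at least 2 alignment columns")
    if any(len(r) != n_cols for r in rows):
        raise ValueError("alignment rows differ in length")

    tree = neighbor_joining(p_distance_matrix(rows), labels)
    arr = np.array([list(r) for r in rows])
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {}
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep_rows = ["".join(row) for row in arr[:, cols]]
        rep_tree = neighbor_joining(p_distance_matrix(rep_rows), labels)
        for split in rep_tree.bipartitions():
            counts[split] = counts.get(split, 0) + 1
    universe = frozenset(labels)
    for node in tree.internal_edges():
        side = frozenset(leaf.name for leaf in node.leaves())
        node.support = counts.get(_canonical(side, universe), 0) / n_reps
    return tree


def cluster_nesting(tree: Tree, member_ids: Iterable[str]) -> bool:
    """True iff the members form a monophyletic group on the unrooted tree.

    Implemented as a bipartition test: some edge must separate exactly the
    members from everything else (leaf edges make single members trivially
    nested; a two-member cluster nests iff it is a cherry).
    """
    members = frozenset(member_ids)
    universe = frozenset(tree.leaf_names())
    missing = members - universe
    if missing:
        raise ValueError(f"cluster members missing from tree: {sorted(missing)}")
    if members == universe:
        return True
    return _canonical(members, universe) in tree.bipartitions(include_trivial=True)
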