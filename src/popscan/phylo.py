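"""p-distance matrices and neighbour-joining trees.

The p-distance of two unphased diploids is the allele-difference fraction
|dosage_a - dosage_b| / 2 averaged over the sites where both are called; it
reduces to the ordinary p-distance for haploid (0/2-coded) samples.

Neighbour joining follows Saitou & Nei with the Studier-Keppler O(n^3)
Q-matrix update; ties in Q are broken by the smallest (i, j) index pair so
output is deterministic. On an additive distance matrix the generating tree
is recovered exactly (topology and branch lengths). Negative branch lengths
are clamped to zero and flagged.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from popscan.genotype_io import MISSING, DataError, GenotypeMatrix

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "Tree",
    "p_distance",
    "neighbor_joining",
    "root_with_outgroup",
]


@dataclasses.dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise distances with an ordered label list.

    ``defined`` marks pairs with at least one shared called site; undefined
    entries hold NaN.
    """

    labels: list[str]
    d: np.ndarray
    defined: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise DataError("distance matrix shape does not match labels")
        if not np.allclose(np.nan_to_num(self.d), np.nan_to_num(self.d.T)):
            raise DataError("distance matrix not symmetric")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


@dataclasses.dataclass
class TreeNode:
    """A node in a (possibly unrooted) tree. Leaves carry a label."""

    label: str | None = None
    children: list[tuple["TreeNode", float]] = dataclasses.field(default_factory=list)
    clamped: bool = False  # a negative NJ branch into this node was clamped

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def newick_fragment(self) -> str:
        if self.is_leaf:
            return self.label or ""
        inner = ",".join(
            f"{child.newick_fragment()}:{length:.10g}" for child, length in self.children
        )
        return f"({inner})"


@dataclasses.dataclass
class Tree:
    """A tree with branch lengths, serializable to newick."""

    root: TreeNode
    rooted: bool = False

    def to_newick(self) -> str:
        return self.root.newick_fragment() + ";"

    def leaves(self) -> list[str]:
        out: list[str] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node.label or "")
            for child, _ in node.children:
                walk(child)

        walk(self.root)
        return out

    def leaf_distances(self) -> dict[tuple[str, str], float]:
        """Path lengths between every leaf pair (for invariance checks)."""
        dists: dict[tuple[str, str], float] = {}

        def walk(node: TreeNode) -> list[tuple[str, float]]:
            if node.is_leaf:
                return [(node.label or "", 0.0)]
            below: list[list[tuple[str, float]]] = []
            for child, length in node.children:
                below.append([(lab, d + length) for lab, d in walk(child)])
            for i in range(len(below)):
                for j in range(i + 1, len(below)):
                    for la, da in below[i]:
                        for lb, db in below[j]:
                            key = (la, lb) if la < lb else (lb, la)
                            dists[key] = da + db
            return [pair for grp in below for pair in grp]

        walk(self.root)
        return dists


def p_distance(gm: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise p-distance over all samples of a genotype matrix.

    d(a, b) = sum_sites |dosage_a - dosage_b| / (2 * n_shared) over sites
    where both samples are non-missing; NaN for pairs with no shared sites.
    """
    if gm.n_samples < 2:
        raise DataError("p_distance needs >= 2 samples")
    called = gm.dosages != MISSING
    C = called.astype(np.float64)
    n_shared = C.T @ C
    # sum_sites |da - db| / 2 via dosage-level indicator products: entry (i, j)
    # of A.T @ B counts sites where sample i carries va and sample j carries vb
    diff = np.zeros_like(n_shared)
    indicators = {
        v: (called & (gm.dosages == v)).astype(np.float64) for v in (0, 1, 2)
    }
    for va in (0, 1, 2):
        for vb in (0, 1, 2):
            if va != vb:
                diff += (abs(va - vb) / 2.0) * (indicators[va].T @ indicators[vb])
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(n_shared > 0, diff / n_shared, np.nan)
    np.fill_diagonal(d, 0.0)
    defined = n_shared > 0
    np.fill_diagonal(defined, True)
    return DistanceMatrix(labels=list(gm.samples), d=d, defined=defined)


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbour joining (Studier-Keppler update).

    Requires every pair defined and >= 3 taxa. Ties in the Q criterion are
    broken by the smallest (i, j) index pair. Negative branch lengths are
    clamped to 0 and flagged on the child node.
    """
    n = len(dm.labels)
    if n < 3:
        raise DataError("neighbour joining needs >= 3 taxa")
    if not dm.defined.all():
        raise DataError("undefined distances present; cannot build tree")
    D = dm.d.copy()
    nodes: list[TreeNode] = [TreeNode(label=lab) for lab in dm.labels]
    active = list(range(n))

    def clamp(length: float, node: TreeNode) -> float:
        if length < 0:
            node.clamped = True
            return 0.0
        return length

    while len(active) > 2:
        r = len(active)
        sub = D[np.ix_(active, active)]
        R = sub.sum(axis=1)
        Q = (r - 2) * sub - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        # row-major argmin = first occurrence = smallest (i, j) pair on ties,
        # and symmetry guarantees bi < bj
        bi, bj = divmod(int(np.argmin(Q)), r)
        i, j = active[bi], active[bj]
        dij = D[i, j]
        li = 0.5 * dij + (R[bi] - R[bj]) / (2.0 * (r - 2))
        lj = dij - li
        parent = TreeNode()
        li = clamp(li, nodes[i])
        lj = clamp(lj, nodes[j])
        parent.children = [(nodes[i], li), (nodes[j], lj)]
        # distances from the new node to every other active node
        new_row = np.zeros(D.shape[0])
        for ak in active:
            if ak in (i, j):
                continue
            new_row[ak] = 0.5 * (D[i, ak] + D[j, ak] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        k = D.shape[0] - 1
        D[k, : k] = new_row
        D[: k, k] = new_row
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [k]

    i, j = active
    length = clamp(D[i, j], nodes[j])
    if nodes[j].is_leaf:
        root = nodes[i]
        root.children = list(root.children) + [(nodes[j], length)]
    else:
        root = nodes[j]
        root.children = list(root.children) + [(nodes[i], length)]
    return Tree(root=root, rooted=False)


def root_with_outgroup(tree: Tree, outgroup: str) -> Tree:
    """Root an (unrooted) tree at the midpoint of the outgroup's pendant edge.

    Leaf-to-leaf path lengths are preserved; rooting twice with the same
    outgroup is idempotent.
    """
    # build adjacency over a cloned node set
    adj: dict[int, list[tuple[int, float]]] = {}
    labels: dict[int, str | None] = {}
    counter = [0]

    def index(node: TreeNode) -> int:
        counter[0] += 1
        return counter[0] - 1

    def walk(node: TreeNode, my_id: int) -> None:
        labels[my_id] = node.label
        adj.setdefault(my_id, [])
        for child, length in node.children:
            cid = index(child)
            adj.setdefault(cid, [])
            adj[my_id].append((cid, length))
            adj[cid].append((my_id, length))
            walk(child, cid)

    root_id = index(tree.root)
    walk(tree.root, root_id)

    out_id = next(
        (i for i, lab in labels.items() if lab == outgroup and len(adj[i]) == 1), None
    )
    if out_id is None:
        raise DataError(f"outgroup {outgroup!r} is not a leaf of the tree")

    # suppress the old root if it became a degree-2 node (unrooted semantics)
    if len(adj[root_id]) == 2 and labels[root_id] is None:
        (a, la), (b, lb) = adj[root_id]
        adj[a] = [(x, l) for x, l in adj[a] if x != root_id] + [(b, la + lb)]
        adj[b] = [(x, l) for x, l in adj[b] if x != root_id] + [(a, la + lb)]
        del adj[root_id]

    (nbr, pend_len) = adj[out_id][0]

    def build(node_id: int, parent_id: int | None) -> TreeNode:
        node = TreeNode(label=labels[node_id])
        for child_id, length in sorted(adj[node_id], key=lambda t: t[0]):
            if child_id == parent_id:
                continue
            node.children.append((build(child_id, node_id), length))
        return node

    root = TreeNode()
    out_leaf = TreeNode(label=outgroup)
    ingroup = build(nbr, out_id)
    root.children = [(out_leaf, pend_len / 2.0), (ingroup, pend_len / 2.0)]
    return Tree(root=root, rooted=True)
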