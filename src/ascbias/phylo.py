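"""Neighbor-joining trees and the distances used to compare them.

Trees are compared two ways: the partition (Penny-Hendy) distance, twice the
number of internal branches whose tip bipartitions appear in only one of the
two trees, and the branch-score distance, the square root of the summed
squared branch-length differences over bipartition-matched branches (branches
present in only one tree count their full length against zero). The
branch-score form reduces to a plain per-branch Euclidean distance whenever
the two topologies agree; when they disagree, the unmatched branches are
exactly "the branch lengths that need to be erased" to reconcile the trees.

Distance matrices themselves are compared with the Frobenius norm of their
difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .types import DistanceMatrix


@dataclass
class PhyloTree:
    """An unrooted tree with tip labels and nonnegative branch lengths."""

    tree: dendropy.Tree
    n_negative_clamped: int = 0

    @property
    def tips(self) -> frozenset[str]:
        return frozenset(leaf.taxon.label for leaf in self.tree.leaf_node_iter())

    def bipartitions(self, include_trivial: bool = True) -> dict[frozenset[str], float]:
        """Tip bipartitions and their branch lengths.

        Each bipartition is canonicalized as the side *not* containing the
        alphabetically first tip. The two child edges of a bifurcating root
        induce the same bipartition; their lengths are summed, so rooted and
        unrooted representations of the same tree agree.
        """
        tips = self.tips
        ref = min(tips)
        n = len(tips)
        out: dict[frozenset[str], float] = {}
        for node in self.tree.preorder_node_iter():
            if node is self.tree.seed_node:
                continue
            side = frozenset(l.taxon.label for l in node.leaf_iter())
            if ref in side:
                side = tips - side
            if not include_trivial and not (1 < len(side) < n - 1):
                continue
            length = float(node.edge.length or 0.0)
            out[side] = out.get(side, 0.0) + length
        return out

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    @classmethod
    def from_newick(cls, source: str) -> "PhyloTree":
        text = Path(source).read_text() if "(" not in str(source) else str(source)
        tree = dendropy.Tree.get(data=text, schema="newick")
        tree.is_rooted = False
        return cls(tree)

    def write_newick(self, path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def neighbor_joining(m: DistanceMatrix) -> PhyloTree:
    """Standard NJ agglomeration with the Q-criterion.

    Ties in Q are broken by the smallest (row, column) index pair in node
    creation order, so the output is deterministic. Negative estimated branch
    lengths are clamped to zero (counted in ``n_negative_clamped``).
    """
    n0 = m.n
    if n0 < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    if not np.all(np.isfinite(m.values)):
        raise ValueError("distance matrix contains non-finite entries")

    tns = dendropy.TaxonNamespace(list(m.labels))
    nodes: list[dendropy.Node] = []
    for label in m.labels:
        node = dendropy.Node(taxon=tns.get_taxon(label))
        nodes.append(node)

    D = m.values.astype(float).copy()
    active = list(range(n0))  # indices into `nodes`, in creation order
    dist = {(i, j): D[i, j] for i in range(n0) for j in range(n0)}
    clamped = 0

    def d(i: int, j: int) -> float:
        return dist[(i, j)] if i <= j else dist[(j, i)]

    while len(active) > 3:
        r = len(active)
        sums = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * d(i, j) - sums[i] - sums[j]
                if best is None or q < best[0] - 1e-15:
                    best = (q, i, j)
        _, i, j = best
        dij = d(i, j)
        bi = 0.5 * dij + (sums[i] - sums[j]) / (2 * (r - 2))
        bj = dij - bi
        if bi < 0:
            clamped += 1
            bi = 0.0
        if bj < 0:
            clamped += 1
            bj = 0.0
        parent = dendropy.Node()
        u = len(nodes)
        nodes.append(parent)
        parent.add_child(nodes[i])
        nodes[i].edge.length = bi
        parent.add_child(nodes[j])
        nodes[j].edge.length = bj
        for k in active:
            if k in (i, j):
                continue
            dist[(min(k, u), max(k, u))] = 0.5 * (d(i, k) + d(j, k) - dij)
        dist[(u, u)] = 0.0
        active = [k for k in active if k not in (i, j)] + [u]

    a, b, c = active
    la = 0.5 * (d(a, b) + d(a, c) - d(b, c))
    lb = 0.5 * (d(a, b) + d(b, c) - d(a, c))
    lc = 0.5 * (d(a, c) + d(b, c) - d(a, b))
    center = dendropy.Node()
    for k, length in ((a, la), (b, lb), (c, lc)):
        if length < 0:
            clamped += 1
            length = 0.0
        center.add_child(nodes[k])
        nodes[k].edge.length = length
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = False
    return PhyloTree(tree, n_negative_clamped=clamped)


# ---------------------------------------------------------------------------
# tree distances
# ---------------------------------------------------------------------------


def _check_same_tips(a: PhyloTree, b: PhyloTree) -> None:
    if a.tips != b.tips:
        raise ValueError(
            f"tip sets differ: only in first {sorted(a.tips - b.tips)}, "
            f"only in second {sorted(b.tips - a.tips)}"
        )


def partition_distance(a: PhyloTree, b: PhyloTree) -> int:
    """Partition (Penny-Hendy) distance between two trees on the same tips.

    Counts the non-trivial bipartitions present in exactly one of the trees —
    for binary trees this is twice the number of conflicting internal
    branches per tree, so two distinct resolved quartets are at distance 2
    and identical topologies at 0.
    """
    _check_same_tips(a, b)
    pa = set(a.bipartitions(include_trivial=False))
    pb = set(b.bipartitions(include_trivial=False))
    return len(pa ^ pb)


def branch_length_distance(a: PhyloTree, b: PhyloTree) -> float:
    """Branch-score distance: sqrt of summed squared branch-length differences.

    Branches are matched by the tip bipartition they induce; a branch present
    in only one tree contributes its length squared. Returns 0 for identical
    trees and, for matching topologies, reduces to the Euclidean distance
    between the two branch-length vectors.
    """
    _check_same_tips(a, b)
    ba = a.bipartitions(include_trivial=True)
    bb = b.bipartitions(include_trivial=True)
    total = 0.0
    for key in set(ba) | set(bb):
        total += (ba.get(key, 0.0) - bb.get(key, 0.0)) ** 2
    return math.sqrt(total)


def frobenius_distance(a: DistanceMatrix, b: DistanceMatrix) -> float:
    """Frobenius norm of the elementwise difference of two distance matrices.

    The second matrix is reordered to the first's label order; a label-set
    mismatch is an error.
    """
    if set(a.labels) != set(b.labels):
        raise ValueError("distance matrices have different label sets")
    b_ord = b.reorder(a.labels)
    return float(np.linalg.norm(a.values - b_ord.values, "fro"))


# ---------------------------------------------------------------------------
# PHYLIP square distance matrix text format
# ---------------------------------------------------------------------------


def write_phylip(m: DistanceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{m.n}\n")
        for label, row in zip(m.labels, m.values):
            fh.write(label + "  " + "  ".join(f"{v:.10f}" for v in row) + "\n")


def read_phylip(path) -> DistanceMatrix:
    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    n = int(lines[0].split()[0])
    labels, rows = [], []
    for line in lines[1 : n + 1]:
        parts = line.split()
        labels.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    values = np.asarray(rows)
    values = (values + values.T) / 2.0  # tolerate printed-precision asymmetry
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(labels, values)
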