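"""Independent brute-force reference implementations used to validate the
package's statistics. These deliberately use scalar loops and naive
enumeration, never the code paths they check."""

from __future__ import annotations

import math

import dendropy
import numpy as np


def fst_two_pops(pa, pb, na, nb, mode):
    """Per-locus loop over the two-population variance-of-frequencies F_ST."""
    vals = []
    for x, y in zip(pa, pb):
        if math.isnan(x) or math.isnan(y):
            continue
        if mode == "equal":
            pbar = (x + y) / 2
            s2 = ((x - pbar) ** 2 + (y - pbar) ** 2) / 2
        else:
            nbar = (na + nb) / 2
            pbar = (na * x + nb * y) / (2 * nbar)
            s2 = (na * (x - pbar) ** 2 + nb * (y - pbar) ** 2) / (2 * nbar)
        den = pbar * (1 - pbar)
        if den > 0:
            vals.append(s2 / den)
    return sum(vals) / len(vals)


def nei_matrix(freq):
    """Naive double loop over population pairs and loci (NaN = missing)."""
    r, L = freq.shape
    out = np.zeros((r, r))
    for x in range(r):
        for y in range(r):
            jx = jy = jxy = 0.0
            for l in range(L):
                px, py = freq[x, l], freq[y, l]
                if math.isnan(px) or math.isnan(py):
                    continue
                qx, qy = 1 - px, 1 - py
                jx += px * px + qx * qx
                jy += py * py + qy * qy
                jxy += px * py + qx * qy
            out[x, y] = -math.log(jxy / math.sqrt(jx * jy))
    out[out < 0] = 0.0
    return out


def rank_average_ties(v):
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(len(v), dtype=float)
    i = 0
    sorted_v = np.asarray(v)[order]
    while i < len(v):
        j = i
        while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def spearman(x, y):
    """Rank-then-Pearson with average ranks for ties."""
    rx, ry = rank_average_ties(x), rank_average_ties(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / math.sqrt((rx @ rx) * (ry @ ry)))


def ols(y, x):
    """Normal-equations OLS returning (slope, intercept, r2, slope_se, resid_var)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    X = np.column_stack([np.ones(n), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    intercept, slope = beta
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1 - rss / tss if tss > 0 else float("nan")
    resid_var = rss / (n - 2)
    slope_se = math.sqrt(resid_var / float(((x - x.mean()) ** 2).sum()))
    return slope, intercept, r2, slope_se, resid_var


def dendropy_bipartition_lengths(tree: dendropy.Tree):
    """Map of tip-set bipartitions to branch lengths via dendropy's encoding."""
    tips = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    ref = min(tips)
    out = {}
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        side = frozenset(l.taxon.label for l in edge.head_node.leaf_iter())
        if ref in side:
            side = tips - side
        out[side] = out.get(side, 0.0) + float(edge.length or 0.0)
    return out, tips


def partition_distance(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> int:
    """Explicit bipartition enumeration (twice the symmetric difference)."""
    ba, tips = dendropy_bipartition_lengths(tree_a)
    bb, _ = dendropy_bipartition_lengths(tree_b)
    n = len(tips)
    sa = {s for s in ba if 1 < len(s) < n - 1}
    sb = {s for s in bb if 1 < len(s) < n - 1}
    return len(sa ^ sb)


def branch_score(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> float:
    """Dictionary-of-bipartitions branch-score distance."""
    ba, _ = dendropy_bipartition_lengths(tree_a)
    bb, _ = dendropy_bipartition_lengths(tree_b)
    total = 0.0
    for key in set(ba) | set(bb):
        total += (ba.get(key, 0.0) - bb.get(key, 0.0)) ** 2
    return math.sqrt(total)


def genic_mask(snps, intervals):
    """All-pairs overlap scan, 1-based inclusive coordinates."""
    from ascbias.types import normalize_chromosome

    out = np.zeros(len(snps), dtype=bool)
    for i, snp in enumerate(snps):
        if snp.key is None:
            continue
        chrom, pos = snp.key
        for c, start, end in intervals:
            if normalize_chromosome(c) == chrom and start <= pos <= end:
                out[i] = True
                break
    return out


def random_binary_tree(labels, rng, blen_low=0.05, blen_high=1.0) -> dendropy.Tree:
    """Random topology by repeated random joins; U(low, high) branch lengths."""
    tns = dendropy.TaxonNamespace(list(labels))
    nodes = [dendropy.Node(taxon=tns.get_taxon(l)) for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = float(rng.uniform(blen_low, blen_high))
        parent.add_child(nodes[j])
        nodes[j].edge.length = float(rng.uniform(blen_low, blen_high))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=nodes[0])
    tree.is_rooted = False
    return tree


def path_distance_matrix(tree: dendropy.Tree, labels):
    """Tip-to-tip path lengths via dendropy's phylogenetic distance matrix."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.distance(taxa[labels[i]], taxa[labels[j]])
    return d
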