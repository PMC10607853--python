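"""Independent brute-force implementations used as test oracles.

Deliberately naive: explicit loops, no shared code with the package.
Tree handling goes through dendropy so patristic distances come from an
independent library.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def bray_curtis_brute(counts: np.ndarray) -> np.ndarray:
    n = counts.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = 0.0
            den = 0.0
            for k in range(counts.shape[1]):
                num += abs(counts[i, k] - counts[j, k])
                den += counts[i, k] + counts[j, k]
            out[i, j] = num / den if den > 0 else 0.0
    return out


def patristic_brute(newick: str, taxon_ids) -> np.ndarray:
    """Tip-to-tip path lengths via dendropy."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(taxon_ids)
    out = np.zeros((n, n))
    for i, a in enumerate(taxon_ids):
        for j, b in enumerate(taxon_ids):
            if i != j:
                out[i, j] = pdm.patristic_distance(taxa[a], taxa[b])
    return out


def weighted_unifrac_brute(newick: str, counts: np.ndarray, taxon_ids,
                           normalized: bool) -> np.ndarray:
    """Per-branch accumulation on a dendropy tree."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    col = {t: k for k, t in enumerate(taxon_ids)}
    rel = counts / counts.sum(axis=1, keepdims=True)
    branches = []
    for edge in tree.preorder_edge_iter():
        if edge.head_node is None or edge.length in (None, 0) or edge.tail_node is None:
            continue
        tips = [leaf.taxon.label for leaf in edge.head_node.leaf_iter()]
        cols = [col[t] for t in tips if t in col]
        if cols:
            branches.append((edge.length, cols))
    n = counts.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = 0.0
            den = 0.0
            for length, cols in branches:
                a = sum(rel[i, c] for c in cols)
                b = sum(rel[j, c] for c in cols)
                num += length * abs(a - b)
                den += length * (a + b)
            if normalized:
                out[i, j] = num / den if den > 0 else 0.0
            else:
                out[i, j] = num
    return out


def mntd_brute(counts: np.ndarray, dist: np.ndarray, weighted: bool) -> float:
    present = [k for k in range(len(counts)) if counts[k] > 0]
    nearest = {}
    for i in present:
        nearest[i] = min(dist[i, j] for j in present if j != i)
    if weighted:
        total = sum(counts[i] for i in present)
        return sum(counts[i] / total * nearest[i] for i in present)
    return sum(nearest.values()) / len(present)


def beta_mntd_brute(ca: np.ndarray, cb: np.ndarray, dist: np.ndarray,
                    weighted: bool) -> float:
    pa = [k for k in range(len(ca)) if ca[k] > 0]
    pb = [k for k in range(len(cb)) if cb[k] > 0]

    def directed(src, src_counts, dst):
        terms = []
        for i in src:
            d = min(dist[i, j] for j in dst)
            terms.append((i, d))
        if weighted:
            total = sum(src_counts[i] for i in src)
            return sum(src_counts[i] / total * d for i, d in terms)
        return sum(d for _, d in terms) / len(terms)

    return 0.5 * (directed(pa, ca, pb) + directed(pb, cb, pa))


def spearman_edges_brute(data: np.ndarray, taxon_ids, r_threshold: float,
                         p_threshold: float) -> set:
    """Edge set via per-pair rank correlation with a t-test p-value."""
    n_samples, n_taxa = data.shape
    edges = set()
    for a in range(n_taxa):
        for b in range(a + 1, n_taxa):
            x, y = data[:, a], data[:, b]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rx = stats.rankdata(x)
            ry = stats.rankdata(y)
            r = np.corrcoef(rx, ry)[0, 1]
            if abs(r) >= 1.0:
                p = 0.0
            else:
                t = r * np.sqrt((n_samples - 2) / (1 - r**2))
                p = 2 * stats.t.sf(abs(t), n_samples - 2)
            if abs(r) > r_threshold and p < p_threshold:
                edges.add(frozenset((taxon_ids[a], taxon_ids[b])))
    return edges


def modularity_brute(graph, communities) -> float:
    """Newman modularity Q = sum_c (L_c / L - (d_c / 2L)^2)."""
    edges = list(graph.edges())
    L = len(edges)
    q = 0.0
    for community in communities:
        community = set(community)
        l_c = sum(1 for a, b in edges if a in community and b in community)
        d_c = sum(graph.degree(v) for v in community)
        q += l_c / L - (d_c / (2 * L)) ** 2
    return q
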