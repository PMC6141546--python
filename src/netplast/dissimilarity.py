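"""Structural dissimilarity D between networks from node-distance distributions.

For each node i of a graph G (undirected projection), P_i(d) is the fraction
of the other N−1 nodes at shortest-path distance d, with a dedicated final
bin for unreachable nodes.  From these the measure combines three terms:

  D(G,H) = w1 * sqrt(J(mu_G, mu_H) / log 2)
         + w2 * |sqrt(NND(G)) − sqrt(NND(H))|
         + (w3/2) * [ sqrt(J(Pa_G, Pa_H) / log 2)
                    + sqrt(J(Pa_Gc, Pa_Hc) / log 2) ]

where mu_G is the mean of the P_i, J the (generalized) Jensen–Shannon
divergence, NND(G) = J(P_1..P_N)/log(diam+1) the network node dispersion,
Pa_G the alpha-centrality-derived node probability distribution (sorted,
alpha = 1/N by default) and Gc the graph complement.  Default weights
(0.45, 0.45, 0.10) are the measure's suggested parameters.  D is
non-negative, symmetric, zero for isomorphic graphs, and bounded by 1 when
the weights sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from . import _graph
from ._kernels import distance_histogram

LOG2 = np.log(2.0)
DEFAULT_WEIGHTS = (0.45, 0.45, 0.10)


@dataclass
class DistanceProfile:
    """Per-node distance distributions of one graph (undirected projection)."""

    node_dists: np.ndarray   # (n, diam + 1); last column = unreachable bin
    mu: np.ndarray           # mean distribution, same length
    nnd: float               # network node dispersion
    diameter: int


@dataclass
class GraphSignature:
    """Everything D needs from one graph, computed once."""

    profile: DistanceProfile
    alpha_dist: np.ndarray            # sorted descending, sums to 1
    alpha_dist_complement: np.ndarray
    n: int


def _entropy(p):
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _jsd_two(p, q):
    """Jensen-Shannon divergence of two distributions (natural log)."""
    m = 0.5 * (p + q)
    return _entropy(m) - 0.5 * _entropy(p) - 0.5 * _entropy(q)


def _jsd_many(dists):
    """Generalized JSD of the rows of a matrix of distributions."""
    mu = dists.mean(axis=0)
    return _entropy(mu) - np.mean([_entropy(row) for row in dists])


def distance_profile(net) -> DistanceProfile:
    """BFS node-distance distributions, their mean, and the NND."""
    n = net.number_of_nodes()
    if n < 2:
        raise ValueError("distance profile needs N >= 2")
    indptr, indices = _graph.to_csr_undirected(net)
    hist, diam = distance_histogram(indptr, indices)
    # hist[:, 0] = unreachable counts, hist[:, d] = counts at distance d
    ncols = max(diam, 1) + 1
    p = np.zeros((n, ncols))
    if diam >= 1:
        p[:, :diam] = hist[:, 1:diam + 1]
    p[:, -1] = hist[:, 0]
    p /= (n - 1)
    mu = p.mean(axis=0)
    j = _jsd_many(p)
    nnd = j / np.log(diam + 1) if diam >= 1 and j > 0 else 0.0
    return DistanceProfile(node_dists=p, mu=mu, nnd=nnd, diameter=diam)


def _alpha_centrality_dist(adj: np.ndarray, alpha=None) -> np.ndarray:
    """Sorted probability distribution of alpha-centrality values.

    x = (I − alpha*A)^{-1} 1 with alpha = 1/N by default (safely inside the
    convergence radius for simple graphs); normalized to sum 1 and sorted
    descending so the distribution is label-free.
    """
    n = adj.shape[0]
    if alpha is None:
        alpha = 1.0 / n
    x = np.linalg.solve(np.eye(n) - alpha * adj, np.ones(n))
    x = np.clip(x, 0.0, None)
    total = x.sum()
    p = x / total if total > 0 else np.full(n, 1.0 / n)
    return np.sort(p)[::-1]


def graph_signature(net, alpha=None) -> GraphSignature:
    """Precompute the distance profile and alpha-centrality distributions."""
    prof = distance_profile(net)
    adj = _graph.undirected_dense_adjacency(net)
    comp = 1.0 - adj
    np.fill_diagonal(comp, 0.0)
    return GraphSignature(
        profile=prof,
        alpha_dist=_alpha_centrality_dist(adj, alpha=alpha),
        alpha_dist_complement=_alpha_centrality_dist(comp, alpha=alpha),
        n=net.number_of_nodes(),
    )


def _pad_mu(a, b):
    """Align two mean-distance distributions: common distance bins, shared
    unreachable bin last."""
    la, lb = len(a), len(b)
    m = max(la, lb)
    pa, pb = np.zeros(m), np.zeros(m)
    pa[:la - 1] = a[:-1]
    pa[-1] = a[-1]
    pb[:lb - 1] = b[:-1]
    pb[-1] = b[-1]
    return pa, pb


def _pad_tail(a, b):
    m = max(len(a), len(b))
    pa, pb = np.zeros(m), np.zeros(m)
    pa[:len(a)] = a
    pb[:len(b)] = b
    return pa, pb


def dissimilarity_from_signatures(sa: GraphSignature, sb: GraphSignature,
                                  weights=DEFAULT_WEIGHTS,
                                  alpha_term=True) -> float:
    w1, w2, w3 = weights
    if not np.isclose(w1 + w2 + w3, 1.0):
        raise ValueError("dissimilarity weights must sum to 1")
    mu_a, mu_b = _pad_mu(sa.profile.mu, sb.profile.mu)
    term1 = w1 * np.sqrt(max(_jsd_two(mu_a, mu_b), 0.0) / LOG2)
    term2 = w2 * abs(np.sqrt(sa.profile.nnd) - np.sqrt(sb.profile.nnd))
    d = term1 + term2
    if alpha_term and w3 > 0:
        pa, pb = _pad_tail(sa.alpha_dist, sb.alpha_dist)
        pac, pbc = _pad_tail(sa.alpha_dist_complement, sb.alpha_dist_complement)
        d += (w3 / 2.0) * (np.sqrt(max(_jsd_two(pa, pb), 0.0) / LOG2)
                           + np.sqrt(max(_jsd_two(pac, pbc), 0.0) / LOG2))
    return float(d)


def dissimilarity(g, h, weights=DEFAULT_WEIGHTS, alpha_term=True,
                  alpha=None) -> float:
    """Structural dissimilarity D between two networks (undirected projection)."""
    return dissimilarity_from_signatures(
        graph_signature(g, alpha=alpha), graph_signature(h, alpha=alpha),
        weights=weights, alpha_term=alpha_term,
    )


def pairwise_dissimilarity(panel, weights=DEFAULT_WEIGHTS, alpha_term=True,
                           alpha=None):
    """All-pairs D over a panel.

    Returns (matrix DataFrame, summary DataFrame, linkage).  The summary
    carries each network's median D and its most dissimilar partner; the
    linkage is an average-linkage (UPGMA) hierarchical clustering of D.
    """
    nets = list(panel)
    names = [g.graph["name"] for g in nets]
    if len(nets) < 2:
        raise ValueError("pairwise dissimilarity needs at least two networks")
    sigs = [graph_signature(g, alpha=alpha) for g in nets]
    k = len(nets)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d[i, j] = d[j, i] = dissimilarity_from_signatures(
                sigs[i], sigs[j], weights=weights, alpha_term=alpha_term)
    matrix = pd.DataFrame(d, index=names, columns=names)
    off = d + np.diag(np.full(k, np.nan))
    summary = pd.DataFrame({
        "network": names,
        "median_D": np.nanmedian(off, axis=1),
        "most_dissimilar": [names[int(np.nanargmax(off[i]))] for i in range(k)],
    }).set_index("network")
    linkage = hierarchy.linkage(squareform(d, checks=False), method="average")
    return matrix, summary, linkage


def linkage_to_newick(linkage, names) -> str:
    """Serialize a scipy linkage as a Newick tree string."""
    tree = hierarchy.to_tree(linkage)

    def walk(node, parent_dist):
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


def compare_dissimilarity_groups(matrix: pd.DataFrame, group_labels):
    """Between-group vs within-group D values, two-sided Wilcoxon rank-sum.

    ``group_labels``: mapping network name -> group (exactly two groups).
    """
    names = list(matrix.index)
    labels = [group_labels[n] for n in names]
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ValueError("need exactly two groups")
    for g in uniq:
        if labels.count(g) < 2:
            raise ValueError(f"group {g!r} needs >= 2 members for within-group D")
    d = matrix.to_numpy()
    between, within = [], []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            (between if labels[i] != labels[j] else within).append(d[i, j])
    stat, p = stats.ranksums(between, within)
    return {"statistic": float(stat), "p_value": float(p),
            "n_between": len(between), "n_within": len(within),
            "median_between": float(np.median(between)),
            "median_within": float(np.median(within))}
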