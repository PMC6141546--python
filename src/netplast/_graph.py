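"""Internal adapters between networkx digraphs and the array forms the kernels use.

Node order is the graph's insertion order throughout, so every seeded
operation downstream is reproducible for a given load order.
"""

from __future__ import annotations

import numpy as np
import networkx as nx


def node_list(net: nx.DiGraph) -> list:
    return list(net.nodes())


def edge_array(net: nx.DiGraph) -> np.ndarray:
    """(m, 2) int array of edges as indices into the node order."""
    idx = {u: i for i, u in enumerate(net.nodes())}
    if net.number_of_edges() == 0:
        return np.empty((0, 2), dtype=np.int64)
    return np.array([(idx[u], idx[v]) for u, v in net.edges()], dtype=np.int64)


def _csr_from_edges(n: int, src: np.ndarray, dst: np.ndarray):
    order = np.argsort(src, kind="stable")
    src = src[order]
    dst = dst[order]
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(indptr, src + 1, 1)
    np.cumsum(indptr, out=indptr)
    return indptr, dst.astype(np.int64)


def to_csr_directed(net: nx.DiGraph):
    """CSR adjacency (indptr, indices) following out-edges."""
    e = edge_array(net)
    return _csr_from_edges(net.number_of_nodes(), e[:, 0], e[:, 1])


def to_csr_undirected(net: nx.DiGraph):
    """Symmetrized CSR adjacency of the undirected projection (deduplicated)."""
    e = edge_array(net)
    lo = np.minimum(e[:, 0], e[:, 1])
    hi = np.maximum(e[:, 0], e[:, 1])
    und = np.unique(lo * net.number_of_nodes() + hi)
    lo = und // net.number_of_nodes()
    hi = und % net.number_of_nodes()
    src = np.concatenate([lo, hi])
    dst = np.concatenate([hi, lo])
    return _csr_from_edges(net.number_of_nodes(), src, dst)


def undirected_edge_array(net: nx.DiGraph) -> np.ndarray:
    """(m_u, 2) deduplicated undirected edges (lo < hi)."""
    e = edge_array(net)
    if len(e) == 0:
        return np.empty((0, 2), dtype=np.int64)
    lo = np.minimum(e[:, 0], e[:, 1])
    hi = np.maximum(e[:, 0], e[:, 1])
    und = np.unique(lo * net.number_of_nodes() + hi)
    return np.column_stack([und // net.number_of_nodes(),
                            und % net.number_of_nodes()])


def total_degrees(net: nx.DiGraph) -> np.ndarray:
    """In+out degree per node, in node order."""
    n = net.number_of_nodes()
    deg = np.zeros(n, dtype=np.int64)
    e = edge_array(net)
    if len(e):
        np.add.at(deg, e[:, 0], 1)
        np.add.at(deg, e[:, 1], 1)
    return deg


def undirected_dense_adjacency(net: nx.DiGraph) -> np.ndarray:
    """Dense 0/1 symmetric adjacency of the undirected projection."""
    n = net.number_of_nodes()
    a = np.zeros((n, n), dtype=np.float64)
    e = edge_array(net)
    if len(e):
        a[e[:, 0], e[:, 1]] = 1.0
        a[e[:, 1], e[:, 0]] = 1.0
    return a
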