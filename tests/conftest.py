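import networkx as nx
import numpy as np
import pytest


def digraph(edges, nodes=None, name="g"):
    g = nx.DiGraph(name=name)
    if nodes is not None:
        g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return g


@pytest.fixture
def directed_cycle3():
    return digraph([("A", "B"), ("B", "C"), ("C", "A")], name="cycle3")


@pytest.fixture
def undirected_path3():
    # A <-> B <-> C as a 4-arc digraph
    return digraph([("A", "B"), ("B", "A"), ("B", "C"), ("C", "B")],
                   name="path3")


@pytest.fixture
def complete_k4():
    g = nx.complete_graph(4, create_using=nx.DiGraph)
    g.graph["name"] = "k4"
    return g


@pytest.fixture
def star10():
    # hub <-> each of 9 leaves
    edges = []
    for i in range(1, 10):
        edges += [("hub", f"L{i}"), (f"L{i}", "hub")]
    return digraph(edges, name="star10")


def random_digraph(n, p, seed, name=None):
    g = nx.gnp_random_graph(n, p, seed=seed, directed=True)
    out = nx.DiGraph(name=name or f"gnp{n}_{seed}")
    out.add_nodes_from(range(n))
    out.add_edges_from(g.edges())
    return out


@pytest.fixture(scope="session")
def small_panel():
    """A 4-network mini-panel for plumbing tests (fast)."""
    from netplast import synthetic

    spec = synthetic.GradientSpec(n_nodes=80, n_edges=800,
                                  lambdas=(0.0, 0.4, 0.8, 1.0), seed=11)
    panel, truth = synthetic.make_gradient_panel(spec)
    return panel, truth


def bfs_distances(net, source):
    """Reference BFS used as the independent distance oracle in tests."""
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in net.successors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def brute_force_efficiency(net):
    """Independent oracle: all-pairs BFS harmonic mean over ordered pairs."""
    n = net.number_of_nodes()
    if n < 2:
        return 0.0
    total = 0.0
    for s in net.nodes():
        for t, d in bfs_distances(net, s).items():
            if t != s:
                total += 1.0 / d
    return total / (n * (n - 1))
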