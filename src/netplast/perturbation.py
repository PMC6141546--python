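"""Site-percolation experiments: random failures (errors) and degree-targeted attacks.

A perturbation removes a fraction ``f`` of nodes together with their edges.
Damage is tracked by two normalized measures against the intact network:

* ``S_f/S_0`` — size of the giant (largest weakly connected) component;
* ``E_f/E_0`` — global efficiency, the mean reciprocal directed shortest-path
  length over ordered pairs, E = (1/(N(N-1))) sum_{i!=j} 1/d_ij, with
  unreachable pairs contributing zero.  Perturbed efficiencies keep the
  intact network's N in the denominator so the ratio stays in [0, 1] and
  hits 0 when every node is gone.

Error curves average many independent removal orders (one uniform random
node permutation per replicate, removed as a growing prefix); attack curves
remove nodes in decreasing total-degree order of the intact network
(static ranking by default, adaptive recomputation behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _graph
from ._kernels import directed_distance_summary, largest_component_size

#: one to a hundred percent of nodes, in steps of one percent
DEFAULT_F_GRID = np.round(np.arange(1, 101) / 100.0, 2)


@dataclass
class DamageCurve:
    """Mean damage trajectory of one network under one perturbation mode."""

    f_grid: np.ndarray
    S_rel: np.ndarray
    E_rel: np.ndarray
    mode: str                      # "error" | "attack"
    n_reps: int = 1
    name: str = ""

    def __post_init__(self):
        self.f_grid = np.asarray(self.f_grid, dtype=float)
        self.S_rel = np.asarray(self.S_rel, dtype=float)
        self.E_rel = np.asarray(self.E_rel, dtype=float)
        if not (len(self.f_grid) == len(self.S_rel) == len(self.E_rel)):
            raise ValueError("f_grid, S_rel, E_rel must have equal length")


def _validate_grid(f_grid):
    f = DEFAULT_F_GRID if f_grid is None else np.asarray(f_grid, dtype=float)
    if np.any(f <= 0) or np.any(f > 1):
        raise ValueError("removal fractions must lie in (0, 1]")
    return f


def _removal_counts(f_grid, n):
    k = np.rint(f_grid * n).astype(np.int64)
    return np.maximum.accumulate(k)  # non-decreasing in f


def giant_component_fraction(net, n_original=None):
    """Largest weakly connected component size over the original node count.

    ``n_original`` lets callers normalize a perturbed graph against the
    intact network's N; defaults to the graph's own node count.
    """
    n = net.number_of_nodes()
    if n_original is None:
        n_original = n
    if n_original == 0:
        return 0.0
    if n == 0:
        return 0.0
    indptr, indices = _graph.to_csr_undirected(net)
    alive = np.ones(n, dtype=np.bool_)
    return largest_component_size(indptr, indices, alive) / n_original


def global_efficiency(net):
    """Mean reciprocal directed distance over ordered pairs (0 for N < 2)."""
    n = net.number_of_nodes()
    if n < 2:
        return 0.0
    indptr, indices = _graph.to_csr_directed(net)
    alive = np.ones(n, dtype=np.bool_)
    return directed_distance_summary(indptr, indices, alive)[0] / (n * (n - 1))


class _DamageEngine:
    """Precomputed CSR forms + intact baselines for repeated masked evaluation."""

    def __init__(self, net):
        self.n = net.number_of_nodes()
        self.indptr_d, self.indices_d = _graph.to_csr_directed(net)
        self.indptr_u, self.indices_u = _graph.to_csr_undirected(net)
        alive = np.ones(self.n, dtype=np.bool_)
        self.S0 = largest_component_size(self.indptr_u, self.indices_u, alive)
        self.E0_raw = directed_distance_summary(self.indptr_d, self.indices_d, alive)[0]
        if self.S0 == 0 or self.E0_raw == 0:
            raise ValueError("network has no edges; damage curves are undefined")

    def measures(self, alive):
        """(S_f/S_0, E_f/E_0) for a keep-mask."""
        if not alive.any():
            return 0.0, 0.0
        s = largest_component_size(self.indptr_u, self.indices_u, alive)
        e = directed_distance_summary(self.indptr_d, self.indices_d, alive)[0]
        return s / self.S0, e / self.E0_raw

    def curve_for_order(self, order, counts):
        """Damage at each cumulative prefix of a removal order."""
        s_rel = np.empty(len(counts))
        e_rel = np.empty(len(counts))
        alive = np.ones(self.n, dtype=np.bool_)
        prev = 0
        for i, k in enumerate(counts):
            if k > prev:
                alive[order[prev:k]] = False
                prev = k
            s_rel[i], e_rel[i] = self.measures(alive)
        return s_rel, e_rel


def simulate_error(net, f_grid=None, n_reps=1000, seed=None):
    """Mean damage under uniformly random node removal.

    One uniform random permutation is drawn per replicate; for each f the
    first round(f*N) nodes of that permutation are removed (cumulative
    prefix removal — identical in distribution to drawing an independent
    uniform subset per f, at a fraction of the cost).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    f = _validate_grid(f_grid)
    eng = _DamageEngine(net)
    counts = _removal_counts(f, eng.n)
    rng = np.random.default_rng(seed)
    s_acc = np.zeros(len(f))
    e_acc = np.zeros(len(f))
    for _ in range(n_reps):
        order = rng.permutation(eng.n)
        s, e = eng.curve_for_order(order, counts)
        s_acc += s
        e_acc += e
    return DamageCurve(f, s_acc / n_reps, e_acc / n_reps, mode="error",
                       n_reps=n_reps, name=net.graph.get("name", ""))


def attack_order(net, strategy="static_degree", seed=None, tie_shuffle=False):
    """Node removal order for a degree-targeted attack.

    static_degree: rank once by total degree of the intact network,
    descending, ties broken by node order (or shuffled when asked).
    adaptive_degree: recompute degrees after every single removal.
    """
    deg = _graph.total_degrees(net).astype(np.float64)
    n = len(deg)
    if tie_shuffle:
        tiebreak = np.random.default_rng(seed).permutation(n)
    else:
        tiebreak = np.arange(n)
    if strategy == "static_degree":
        return np.lexsort((tiebreak, -deg))
    if strategy == "adaptive_degree":
        deg = deg.copy()
        alive = np.ones(n, dtype=np.bool_)
        order = np.empty(n, dtype=np.int64)
        e = _graph.edge_array(net)
        out_nbrs = [[] for _ in range(n)]
        in_nbrs = [[] for _ in range(n)]
        for u, v in e:
            out_nbrs[u].append(v)
            in_nbrs[v].append(u)
        key = -(deg * n) + tiebreak  # smaller = removed earlier
        for step in range(n):
            cand = np.where(alive)[0]
            best = cand[np.argmin(key[cand])]
            order[step] = best
            alive[best] = False
            for v in out_nbrs[best]:
                if alive[v]:
                    deg[v] -= 1
                    key[v] = -(deg[v] * n) + tiebreak[v]
            for u in in_nbrs[best]:
                if alive[u]:
                    deg[u] -= 1
                    key[u] = -(deg[u] * n) + tiebreak[u]
        return order
    raise ValueError(f"unknown attack strategy: {strategy!r}")


def simulate_attack(net, f_grid=None, strategy="static_degree", seed=None,
                    tie_shuffle=False):
    """Damage under removal in decreasing order of degree centrality."""
    f = _validate_grid(f_grid)
    eng = _DamageEngine(net)
    counts = _removal_counts(f, eng.n)
    order = attack_order(net, strategy=strategy, seed=seed,
                         tie_shuffle=tie_shuffle)
    s, e = eng.curve_for_order(order, counts)
    return DamageCurve(f, s, e, mode="attack", n_reps=1,
                       name=net.graph.get("name", ""))


def damage_curves(net, f_grid=None, n_reps=1000, strategy="static_degree",
                  seed=None):
    """Convenience: (error_curve, attack_curve) for one network."""
    return (simulate_error(net, f_grid=f_grid, n_reps=n_reps, seed=seed),
            simulate_attack(net, f_grid=f_grid, strategy=strategy, seed=seed))


def curves_to_records(curves):
    """Flatten DamageCurves into rows for io.write_table."""
    rows = []
    for c in curves:
        for i, f in enumerate(c.f_grid):
            rows.append({"network": c.name, "mode": c.mode, "f": float(f),
                         "S_rel": float(c.S_rel[i]), "E_rel": float(c.E_rel[i])})
    return rows
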