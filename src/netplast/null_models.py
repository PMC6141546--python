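"""Matched random-graph ensembles: Erdős–Rényi and Barabási–Albert analogs.

Each real network gets two 100-replicate null ensembles at matched size:

* ER — directed G(n, m): exactly m distinct non-loop edges, uniform;
* BA — a growing directed network in which every arriving node emits k
  out-edges with k drawn (with replacement) from the real network's
  empirical out-degree distribution, truncated to the number of existing
  nodes; targets follow preferential attachment on in-degree with +1
  additive smoothing.  Edge counts match the real m in expectation.

Replicates are profiled with the 14 topological features and their
dissimilarity D to the real network; the per-feature z of the real value
against the ensemble gives a normal-approximation p (the 100-replicate
empirical tail is reported alongside, its resolution being only 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from . import topology
from .dissimilarity import (DEFAULT_WEIGHTS,
    dissimilarity_from_signatures, graph_signature)


def _er_digraph(n, m, rng):
    if m > n * (n - 1):
        raise ValueError(f"m={m} exceeds the n(n-1)={n * (n - 1)} possible arcs")
    idx = rng.choice(n * (n - 1), size=m, replace=False)
    i = idx // (n - 1)
    r = idx % (n - 1)
    j = r + (r >= i)
    net = nx.DiGraph(name="ER")
    net.add_nodes_from(range(n))
    net.add_edges_from(zip(i.tolist(), j.tolist()))
    return net


def generate_er(n, m, seed=None):
    """Directed G(n, m): exactly m distinct non-loop edges, uniformly sampled."""
    rng = np.random.default_rng(seed)
    return _er_digraph(n, m, rng)


def generate_ba(real, seed=None):
    """Growing directed analog of a real network (out-degree-seeded BA).

    The number of seed nodes is max(1, smallest drawn out-degree); each
    later node emits min(k, #existing) out-edges, targets sampled without
    replacement with probability proportional to in-degree + 1.
    """
    n = real.number_of_nodes()
    m = real.number_of_edges()
    if n < 2 or m < 1:
        raise ValueError("BA analog needs a real network with N >= 2, m >= 1")
    rng = np.random.default_rng(seed)
    out_degrees = np.array([d for _, d in real.out_degree()], dtype=np.int64)
    draws = rng.choice(out_degrees, size=n, replace=True)
    n_seed = max(1, int(draws.min()))
    indeg = np.zeros(n, dtype=np.float64)
    edges = []
    for t in range(n_seed, n):
        k = min(int(draws[t]), t)
        if k == 0:
            continue
        w = indeg[:t] + 1.0
        # weighted sampling without replacement (exponential-sort keys)
        keys = rng.exponential(size=t) / w
        targets = np.argpartition(keys, k - 1)[:k]
        for v in targets:
            edges.append((t, int(v)))
            indeg[v] += 1
    net = nx.DiGraph(name="BA")
    net.add_nodes_from(range(n))
    net.add_edges_from(edges)
    return net


@dataclass
class EnsembleSummary:
    """Feature statistics of a null ensemble matched to one real network."""

    network_name: str
    model: str                       # "ER" | "BA"
    n_reps: int
    feature_stats: pd.DataFrame      # real, mean, sd, z, p_normal, p_empirical, degenerate
    d_to_real: np.ndarray            # per-replicate D to the real network

    @property
    def mean_d_to_real(self) -> float:
        return float(np.mean(self.d_to_real))


def ensemble_profile(real, model, n_reps=100, seed=None, with_features=True,
                     weights=DEFAULT_WEIGHTS, alpha_term=True,
                     modularity_seed=0) -> EnsembleSummary:
    """Characterize a matched null ensemble against a real network.

    For every replicate: the 14 features (optional) and its dissimilarity D
    to the real network.  Per-feature z = (real − ensemble mean)/sd; sd = 0
    features are flagged degenerate (z undefined, not an error).
    """
    if n_reps < 2:
        raise ValueError("an ensemble needs n_reps >= 2")
    if model not in ("ER", "BA"):
        raise ValueError(f"unknown null model: {model!r}")
    rng = np.random.default_rng(seed)
    n, m = real.number_of_nodes(), real.number_of_edges()
    real_sig = graph_signature(real)
    feats = []
    d_vals = np.empty(n_reps)
    for r in range(n_reps):
        if model == "ER":
            g = _er_digraph(n, m, rng)
        else:
            g = generate_ba(real, seed=rng.integers(2 ** 31))
        d_vals[r] = dissimilarity_from_signatures(
            real_sig, graph_signature(g), weights=weights,
            alpha_term=alpha_term)
        if with_features:
            feats.append(topology.compute_features(
                g, modularity_seed=modularity_seed))

    if with_features:
        fdf = pd.DataFrame(feats)
        real_feats = topology.compute_features(real, modularity_seed=modularity_seed)
        rows = []
        for name in topology.FEATURE_NAMES:
            x = fdf[name].to_numpy()
            mean, sd = float(x.mean()), float(x.std(ddof=1))
            real_x = float(real_feats[name])
            degenerate = sd == 0.0
            z = np.nan if degenerate else (real_x - mean) / sd
            p_norm = np.nan if degenerate else 2.0 * stats.norm.sf(abs(z))
            p_emp = (1.0 + np.sum(np.abs(x - mean) >= abs(real_x - mean))) / (n_reps + 1.0)
            rows.append({"feature": name, "real": real_x, "mean": mean,
                         "sd": sd, "z": z, "p_normal": p_norm,
                         "p_empirical": p_emp, "degenerate": degenerate})
        feature_stats = pd.DataFrame(rows).set_index("feature")
    else:
        feature_stats = pd.DataFrame()

    return EnsembleSummary(network_name=real.graph.get("name", ""),
                           model=model, n_reps=n_reps,
                           feature_stats=feature_stats, d_to_real=d_vals)


def ensemble_d_to_real(real, model, n_reps=100, seed=None, **kw) -> float:
    """Mean D of a null ensemble to its real counterpart (D_ER or D_BA)."""
    summ = ensemble_profile(real, model, n_reps=n_reps, seed=seed,
                            with_features=False, **kw)
    return summ.mean_d_to_real
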