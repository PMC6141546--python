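"""Synthetic inputs with the statistical structure the analyses assume.

Two generators replace the downloaded data so every stage runs, is seeded,
and is validated against designed ground truth:

* a network panel spanning a homogeneous ↔ scale-free gradient: each
  network is a directed weighted-pair graph whose attachment propensities
  interpolate between uniform (λ=0, an exact directed G(n, m) draw) and a
  fixed heavy-tailed (Zipf-like) propensity sequence (λ=1, scale-free-like
  degree tails), with the heterogeneity split between in- and out-
  propensities.  The dial moves the degree distribution continuously from
  near-Poissonian to heavy-tailed at matched node/edge counts.  Per-network
  edge counts are jittered within ±5%% of the target m so raw connectivity
  features vary while matched-ensemble deviations (D_ER, D_BA) and the
  normalized damage curves do not — the multi-dimensional variation a real
  tissue panel shows.

* a group-structured accessibility matrix: negative-binomial counts
  converted to tags-per-million.  The "ESC" group draws from an even
  expected profile at a higher baseline; the "Adult" group concentrates its
  (lower) signal into a minority of regions, with an evenness dial in
  [0, 1] — 1 means both groups even (null case), smaller values shift more
  Adult signal mass into few regions, lowering Adult entropy by design.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .accessibility import AccessibilityMatrix, REGION_CLASSES
from .io import NetworkPanel


@dataclass
class GradientSpec:
    """A panel of networks along the λ heterogeneity gradient.

    ``gamma`` is the exponent of the heavy-tailed propensity sequence,
    ``rho`` the share of heterogeneity placed on in- (vs out-) propensities,
    ``m_jitter`` the relative half-width of the per-network edge-count
    jitter around ``n_edges``.
    """

    n_nodes: int = 300
    n_edges: int = 4500
    lambdas: tuple = tuple(np.round(np.arange(0, 11) / 10, 1)) + (0.5,)
    gamma: float = 0.75
    rho: float = 0.5
    m_jitter: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes <= 0 or self.n_edges <= 0:
            raise ValueError("node and edge counts must be positive")
        if self.n_edges * (1 + self.m_jitter) > self.n_nodes * (self.n_nodes - 1):
            raise ValueError("more edges than ordered node pairs")
        if any(l < 0 or l > 1 for l in self.lambdas):
            raise ValueError("lambda values must lie in [0, 1]")
        if not 0 <= self.m_jitter < 1:
            raise ValueError("m_jitter must lie in [0, 1)")


@dataclass
class AccessibilitySpec:
    """Group-structured accessibility counts with a designed entropy gap."""

    regions_per_class: int = 300
    samples_per_group: int = 8
    baseline_mean: float = 200.0      # expected Adult counts per region
    esc_gain: float = 1.5             # ESC baseline multiplier (more accessible)
    dispersion: float = 5.0           # NB size parameter (smaller = noisier)
    evenness: float = 0.5             # 1 = Adult as even as ESC (null case)
    concentration_scale: float = 6.0  # decay strength at evenness 0
    seed: int = 0

    def __post_init__(self):
        if self.regions_per_class < 2 or self.samples_per_group < 2:
            raise ValueError("need >= 2 regions per class and samples per group")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if not 0 <= self.evenness <= 1:
            raise ValueError("evenness dial must lie in [0, 1]")


def mixture_network(n, m, lam, seed=None, gamma=0.75, rho=0.5, name=None):
    """One λ-mixture digraph with exactly m edges.

    Every ordered pair (i, j) carries weight wout_i * win_j, where the out-
    and in-propensities interpolate between uniform and a shuffled Zipf-like
    sequence z_r = r^(-gamma) (normalized to mean 1): win = (1 - λρ) + λρ·z,
    wout = (1 - λ(1-ρ)) + λ(1-ρ)·z, with independent shuffles so in- and
    out-hubs need not coincide.  The m distinct non-loop pairs with the
    smallest Exp/weight keys form the edge set — a weighted sample without
    replacement, reducing to an exact uniform G(n, m) draw at λ = 0.
    """
    if m > n * (n - 1):
        raise ValueError(f"m={m} exceeds the n(n-1)={n * (n - 1)} possible arcs")
    if not 0 <= lam <= 1:
        raise ValueError("lambda must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    z = np.arange(1, n + 1, dtype=float) ** (-gamma)
    z /= z.mean()
    win = (1 - lam * rho) + lam * rho * z[rng.permutation(n)]
    wout = (1 - lam * (1 - rho)) + lam * (1 - rho) * z[rng.permutation(n)]
    weights = np.outer(wout, win)
    np.fill_diagonal(weights, np.nan)          # no self-loops
    keys = rng.exponential(size=(n, n)) / weights
    keys[np.isnan(keys)] = np.inf
    idx = np.argpartition(keys.ravel(), m - 1)[:m]
    src, dst = idx // n, idx % n
    net = nx.DiGraph()
    net.add_nodes_from(range(n))
    net.add_edges_from(zip(src.tolist(), dst.tolist()))
    net.graph["name"] = name or f"lam{lam:.2f}"
    net.graph["lambda"] = float(lam)
    return nx.relabel_nodes(net, {i: f"TF{i:04d}" for i in range(n)})


def make_gradient_panel(spec: GradientSpec):
    """Seeded λ-gradient panel plus its truth table (λ per network)."""
    rng = np.random.default_rng(spec.seed)
    nets, rows = [], []
    for i, lam in enumerate(spec.lambdas):
        name = f"net{i:02d}_lam{lam:.1f}"
        m_i = int(round(spec.n_edges
                        * rng.uniform(1 - spec.m_jitter, 1 + spec.m_jitter)))
        g = mixture_network(spec.n_nodes, m_i, lam,
                            seed=int(rng.integers(2 ** 31)),
                            gamma=spec.gamma, rho=spec.rho, name=name)
        nets.append(g)
        rows.append({"network": name, "lambda": float(lam),
                     "n_nodes": spec.n_nodes, "n_edges": g.number_of_edges()})
    truth = pd.DataFrame(rows).set_index("network")
    return NetworkPanel(networks=nets, species_tag="synthetic"), truth


def make_accessibility(spec: AccessibilitySpec):
    """Seeded accessibility matrix plus designed truth (expected profiles).

    Expected Adult signal decays exponentially over the (arbitrary) region
    order at rate concentration_scale * (1 − evenness); ESC signal is flat.
    """
    rng = np.random.default_rng(spec.seed)
    r, s = spec.regions_per_class, spec.samples_per_group
    esc_cols = [f"ESC_{i:02d}" for i in range(s)]
    adult_cols = [f"Adult_{i:02d}" for i in range(s)]
    rate = spec.concentration_scale * (1.0 - spec.evenness)

    frames, region_rows, truth_rows = [], [], []
    pos = 0
    for cls in REGION_CLASSES:
        u = np.linspace(0.0, 1.0, r)
        w_adult = np.exp(-rate * u)
        w_adult *= r / w_adult.sum()          # mean weight 1
        mu_esc = np.full(r, spec.baseline_mean * spec.esc_gain)
        mu_adult = spec.baseline_mean * w_adult

        def nb(mu_vec, cols):
            theta = spec.dispersion
            p = theta / (theta + mu_vec)
            return np.column_stack([
                rng.negative_binomial(theta, p) for _ in cols]).astype(float)

        counts = np.column_stack([nb(mu_esc, esc_cols), nb(mu_adult, adult_cols)])
        ids = [f"{cls}_{i:04d}" for i in range(r)]
        frames.append(pd.DataFrame(counts, index=ids,
                                   columns=esc_cols + adult_cols))
        for i, rid in enumerate(ids):
            region_rows.append({"chrom": "chrS", "start": pos, "end": pos + 5000,
                                "id": rid, "cls": cls})
            pos += 10000
        pe = np.full(r, 1.0 / r)
        pa = w_adult / w_adult.sum()
        truth_rows.append({
            "region_class": cls,
            "expected_entropy_ESC": float(-(pe * np.log(pe)).sum()),
            "expected_entropy_Adult": float(-(pa[pa > 0] * np.log(pa[pa > 0])).sum()),
        })

    values = pd.concat(frames)
    # tags-per-million normalization (entropy is invariant to it)
    values = values / values.sum(axis=0) * 1e6
    regions = pd.DataFrame(region_rows).set_index("id")
    groups = pd.Series({**{c: "ESC" for c in esc_cols},
                        **{c: "Adult" for c in adult_cols}}, name="group")
    am = AccessibilityMatrix(values=values, regions=regions, groups=groups)
    truth = pd.DataFrame(truth_rows).set_index("region_class")
    truth["designed_gap"] = (truth["expected_entropy_ESC"]
                             - truth["expected_entropy_Adult"])
    return am, truth


def write_panel(panel, directory, truth=None):
    """Write a panel as one edge list per network (+ optional truth TSV)."""
    import os

    from .io import write_edge_list

    os.makedirs(directory, exist_ok=True)
    for net in panel:
        write_edge_list(net, os.path.join(directory, net.graph["name"] + ".txt"))
    if truth is not None:
        truth.to_csv(os.path.join(directory, "truth.tsv"), sep="\t")


def write_accessibility(am, directory):
    """Write the BED / matrix / groups triplet consumed by load_accessibility."""
    import os

    os.makedirs(directory, exist_ok=True)
    bed = am.regions.reset_index()[["chrom", "start", "end", "id", "cls"]]
    bed.to_csv(os.path.join(directory, "regions.bed"), sep="\t",
               header=False, index=False)
    am.values.to_csv(os.path.join(directory, "matrix.tsv"), sep="\t")
    am.groups.rename("group").to_csv(os.path.join(directory, "groups.tsv"),
                                     sep="\t")
    return (os.path.join(directory, "regions.bed"),
            os.path.join(directory, "matrix.tsv"),
            os.path.join(directory, "groups.tsv"))
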