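# netplast

Structural robustness profiling of tissue-specific transcription factor
(TF) networks.

Condition-specific TF–TF networks — directed graphs in which an edge
regulator → target records a regulator motif inside an accessible DNase I
footprint near the target's TSS — differ in how well they withstand
structural damage. `netplast` quantifies that behavior and explains it
structurally: it simulates random failures (*errors*) and degree-targeted
*attacks* on each network, summarizes the gap between the two responses as
a vulnerability score, profiles 14 topological features, measures
structural dissimilarity *D* between networks and against matched
Erdős–Rényi (ER) and Barabási–Albert (BA) null ensembles, fits predictive
models of vulnerability, and contrasts chromatin-accessibility evenness
(entropy) between sample groups. A seeded synthetic-data module generates
network panels along a homogeneous ↔ scale-free gradient and
group-structured accessibility matrices so the entire pipeline runs and is
validated without any download.

## The statistics at the core

For a network with `N` nodes, removing a fraction `f` of nodes yields two
normalized damage measures: the relative giant (weakly connected)
component size `S_f/S_0`, and the relative global efficiency `E_f/E_0`
with

    E = 1/(N(N-1)) * sum_{i != j} 1/d_ij,

where `d_ij` is the directed shortest-path length and unreachable pairs
contribute zero. Errors remove nodes uniformly at random (mean over many
replicates); attacks remove nodes in decreasing total-degree order. The
**error–attack deviation** over the removal grid of `n` fractions,

    Δea = sqrt( (1/n) * sum_f (e_f - a_f)^2 ),

is computed for each damage measure, and the **vulnerability** of a
network is `(Δea_S + Δea_E)/2`. Small vulnerability means attacks hurt
little more than random failure — the signature of a homogeneous, ER-like
topology, as in embryonic stem cell (ESC) networks; heavy-tailed networks
are "robust yet fragile" and score high.

Structural dissimilarity `D(G,H)` compares node-distance distributions
(Jensen–Shannon divergences of their means and dispersions, plus a small
α-centrality term) with weights (0.45, 0.45, 0.10); `D_ER` and `D_BA` are
a network's mean `D` to 100-replicate matched null ensembles, placing it
on the homogeneous ↔ heterogeneous axis.

## Worked example

`examples/01_robustness_ranking.py` builds a four-network gradient panel
(λ = 0 is an exact directed G(n, m) draw, λ = 1 a heavy-tailed network at
matched size), simulates 200-replicate error curves plus attack curves on
a 10-point removal grid, and ranks the networks:

```
     network    dea_S    dea_E  vulnerability  rank
net00_lam0.0 0.020637 0.045524       0.033080     1
net01_lam0.3 0.053828 0.056119       0.054974     2
net02_lam0.6 0.049474 0.073921       0.061698     3
net03_lam1.0 0.060477 0.089978       0.075227     4
```

Vulnerability rises monotonically with heterogeneity: the homogeneous
network tolerates attacks almost as well as random failure
(Δea_S ≈ 0.02), while in the λ = 1 network targeted hub removal opens a
gap four times larger on the efficiency curve. The other example scripts
cover the feature profile, the `D` matrix and dendrogram
(`03_dissimilarity_dendrogram.py` shows the lone homogeneous network as
every heterogeneous network's most dissimilar partner), null-ensemble
placement with vulnerability prediction (`D_ER` attains the lowest
univariate cross-validated MSE, with a positive slope), and the
accessibility-entropy contrast (ESC-like samples significantly more even,
Wilcoxon rank-sum p ≈ 8e-4 at the generator's default effect size).

A thin CLI mirrors the library: `netplast simulate networks`, `perturb`,
`robustness`, `features`, `dissim`, `nullmodels`, `predict`,
`accessibility`, and `profile --config config.yaml` for the full
end-to-end bundle with a reproducibility manifest.

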