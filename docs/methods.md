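# Methods

## Scope and model

`netplast` treats a cell type's regulatory state as a directed, simple,
unweighted TF–TF graph: nodes are transcription factors, an edge
regulator → regulated means the regulator is active at the target's
proximal regulatory region. Self-loops are dropped and duplicate edges
collapsed at load time (both flag-reversible and counted in the log);
every reported density follows the loopless directed convention
m/(N(N−1)), and all percolation and distance machinery assumes simple
graphs. Node order is fixed by first appearance in the input file, so all
seeded computations are bit-reproducible across runs and platforms.

## Perturbation experiments

Structural robustness is probed by site percolation. A removal grid of
fractions `f ∈ (0, 1]` (default 0.01 steps; the tests and the acceptance
script use 0.05 steps — see *Problem sizes* below) maps each `f` to
`round(f·N)` removed nodes, forced non-decreasing in `f`.

*Errors*: one uniform random node permutation per replicate; the first
`round(f·N)` entries are removed cumulatively. This prefix scheme is
identical in distribution to drawing an independent uniform subset at each
`f` and costs one permutation per replicate; the test suite checks the
Monte-Carlo means against exhaustive subset enumeration on graphs small
enough to enumerate. The default is 1000 replicates.

*Attacks*: nodes are removed in decreasing total (in+out) degree of the
intact network, ties broken by node order (deterministic; a seeded tie
shuffle is available, and averaging shuffled attacks on a regular graph
reproduces the error curve, which the suite asserts). An adaptive variant
that recomputes degrees after every removal is provided behind a flag but
off by default: the static ranking is the canonical "remove in decreasing
order of degree centrality" reading, and the choice is recorded in the run
manifest.

Damage is tracked by (a) the size of the largest *weakly* connected
component relative to the intact network — weak connectivity matches the
undirected percolation framing of attack-tolerance theory and avoids the
near-empty strong components of sparse digraphs — and (b) global
efficiency `E = (1/(N(N−1))) Σ_{i≠j} 1/d_ij` on *directed* distances,
unreachable pairs contributing zero. Perturbed efficiencies keep the
intact `N` in the denominator, so `E_f/E_0 ∈ [0, 1]` and both measures hit
exactly 0 at `f = 1`.

The error–attack deviation `Δea = sqrt(mean_f (e_f − a_f)²)` is computed
over the full grid including `f = 1` (where both curves are 0), separately
for the component and efficiency curves; vulnerability is their mean.
Rankings attach a leave-one-out z-score per network and, when a two-group
labelling is supplied, a two-sided Wilcoxon rank-sum on vulnerability
(the group test is our choice; no particular test is canonical here).

Implementation note: all BFS work runs through numba kernels over CSR
arrays with an alive-mask, so percolation never rebuilds subgraphs; the
efficiency sum uses a bit-parallel multi-source BFS (64 frontiers per
machine word), about 60× faster than per-source BFS at N = 500, which is
what makes 100-replicate curves over ensembles of hundreds of networks
cheap. A plain per-source reference kernel is kept alongside and the suite
checks agreement.

## Topological features

The 14-feature profile uses mixed conventions, chosen for internal
consistency and recorded in every run manifest: size, edge count,
mean degree 2m/N, directed density; diameter and average path length over
*reachable* directed ordered pairs (disconnectedness warns, never yields
NaN); efficiency shared bit-for-bit with the perturbation module;
clustering (global transitivity), clique number and modularity on the
undirected projection; assortativity as the Pearson correlation of source
and target total degrees over directed edges; reciprocity as the fraction
of edges whose reverse exists. Modularity is the Newman Q of a seeded
multilevel (Louvain) partition of the undirected projection; optimizer and
seed are recorded, and brute-force Q evaluations on planted-partition
graphs anchor the tests.

Degree entropy deserves its own paragraph because two inequivalent
conventions circulate. The entropy of the *degree-value distribution*
(p_k = fraction of nodes with total degree exactly k) is 0 for regular
graphs and log k for k uniformly occupied values; `degree_entropy()`
computes this by default. The entropy of the *normalized degree sequence*
(p_i = d_i/Σd) is maximal, log N, for regular graphs and is depressed by
hubs. Only the sequence convention reproduces the qualitative structure
this framework is built on — ER ensembles scoring above BA ensembles at
matched size, homogeneous ESC-like networks scoring distinctively high,
and magnitudes near log N (≈ 5.8–6.3 for networks of ~520 TFs) — whereas
the value-class convention inverts the ER/BA direction at these densities
(simulation at N = 521, m = 14000: sequence entropy ER 6.25 > BA 5.78;
value-class ER 3.35 < BA 4.07). The feature vector therefore uses
`kind="sequence"`; both kinds are exposed and documented.

## Structural dissimilarity D

For each node, the distance distribution P_i(d) over the other N−1 nodes
is computed by BFS on the undirected projection, with a dedicated final
bin for unreachable nodes. D combines (w1, w2, w3) = (0.45, 0.45, 0.10):

1. `w1 · sqrt(JSD(μ_G, μ_H)/log 2)` on the mean distance distributions,
   aligned on common distance bins with the unreachable bin kept last;
2. `w2 · |sqrt(NND(G)) − sqrt(NND(H))|`, where the network node dispersion
   NND = JSD(P_1…P_N)/log(diam+1) measures heterogeneity of the per-node
   distributions;
3. `(w3/2) · [sqrt(JSD(Pα_G, Pα_H)/log 2) + same for the complements]`,
   where Pα is the sorted, normalized α-centrality vector
   x = (I − αA)^(−1)·1 with α = 1/N (safely inside the convergence radius
   for simple graphs; configurable and recorded). Shorter vectors are
   zero-padded. The α parameterization is our implementation of the
   published construction; the term is isolated behind a switch so the
   first two terms are independently testable.

D is non-negative, symmetric, zero on isomorphic graphs (asserted under
random relabelings), and bounded by 1 when the weights sum to 1. It is
computed on the undirected projection — the measure is defined for
undirected graphs and no directed variant is canonical. Pairwise D
matrices come with per-network median D, most-dissimilar partner, and an
average-linkage (UPGMA) clustering exported as Newick; the linkage choice
is ours and recorded. Per-graph signatures (distance profile +
α-centrality vectors) are computed once and reused, which makes
100-replicate ensemble dissimilarities linear rather than quadratic in
ensemble size.

A practical limitation worth knowing: on dense graphs the measure loses
resolution, because almost all pairs sit at distance 2 and every μ looks
alike. At directed density ≈ 0.05 (the regime of real TF networks, and of
all defaults here) a growth-family network shows D_ER ≈ 0.19–0.21 and
D_BA ≈ 0.04 against 50-replicate ensembles — the magnitudes reported for
real tissue panels — while at density 0.10 the same contrast compresses
to D_ER ≈ 0.06. This is why the synthetic panel is scaled by density, not
by mean degree (below).

## Null models

ER analogs are exact directed G(n, m) draws (uniform distinct non-loop
ordered pairs) — matching node *and* edge counts exactly, not G(n, p).
BA analogs grow: each arriving node emits k out-edges with k drawn with
replacement from the real network's empirical out-degree distribution,
truncated to the number of existing nodes; targets are sampled without
replacement with probability ∝ in-degree + 1 (additive "zero-appeal"
smoothing); the seed block has max(1, smallest draw) nodes. Realized edge
counts match the real m in expectation (exact matching is impossible with
independent draws; the shortfall from early-arrival truncation is < 5% at
N = 500 and the realized distribution is reported). Ensemble profiles
record per-feature mean/sd over the replicates, the real network's
z-score, a two-sided normal-approximation p, and the empirical tail
probability alongside (with 100 replicates the empirical resolution is
only 0.01, hence both). Features with zero ensemble sd (e.g. size against
an ER ensemble) are flagged degenerate, never an error. Calibration: when
the "real" network is itself an ER draw, ~95% of non-degenerate feature
z-scores against its own ER ensemble fall inside |z| < 2 (asserted at the
0.8 level over 3 draws in the suite, the binomial floor for ~30 checks).

## Prediction

The feature matrix holds the 14 features plus D_ER and D_BA (16
predictors) and vulnerability as response. PCA standardizes columns,
drops constant ones with a warning, and signs each component so its
largest-magnitude loading is positive. Univariate fits are closed-form
simple regressions scored by test MSE under seeded, shuffled, size-
balanced k-fold CV (default 5); with panels of only 12–41 networks a
single split is noisy, so rankings use the mean CV MSE over 20 fold
seeds, and `cv_mse_spread` reports the spread. The random forest uses
1000 trees, p/3 features per split, unlimited depth — the standard
regression defaults — on the 14 features only; importances are the
impurity-based mean decrease in MSE from the all-data fit.

## Chromatin accessibility

The accessibility module consumes an already-aggregated region × sample
tags-per-million matrix, BED region definitions (0-based half-open,
5 kb promoter windows centered on the TSS for this module) with classes
gene_promoter / tf_promoter / enhancer, and a sample → group map; read
alignment and tag aggregation are upstream of this package. Group mean
accessibility is the arithmetic mean per region per group, contrasted by
rank-sum per region class. Accessibility entropy is computed **per
sample** over the regions of one class: counts are normalized to a
probability vector and H = −Σ p log p (nats; base configurable). The
per-sample reading admits a group test (two-sided Wilcoxon rank-sum on
the sample entropies), which is the analysis the framework reports;
pooled per-group entropy is available behind a flag. Entropy is invariant
to per-sample rescaling, so TPM normalization choices cannot affect it;
Schur-concavity (evening two unequal values raises H) is spot-checked.

## Synthetic study conditions

The network generator is a static weighted-pair sampler: ordered pair
(i, j) carries weight wout_i · win_j, with propensities interpolating
between uniform and a shuffled Zipf-like sequence r^(−γ) (γ = 0.75,
normalized to mean 1), heterogeneity split evenly between in- and out-
propensities (ρ = 0.5, independent shuffles so in- and out-hubs need not
coincide). The m smallest Exp/weight keys give a weighted sample of
distinct edges, which at λ = 0 is an *exact* uniform directed G(n, m)
draw and at λ = 1 a heavy-tailed network (max/mean total degree > 4 at
the default sizes). A growing-attachment mixture was rejected after
measurement: growth with uniform attachment is structurally far from
G(n, m), so such a panel is discontinuous at the homogeneous end, and
growth leaks mechanical side-channels (growth edges can never be
reciprocated, making reciprocity a deterministic linear function of λ).
The static dial is smooth across the whole range including both
endpoints. Its own limitation: λ = 1 networks are heavy-tailed but do not
carry the growth signature of the BA family, so they remain closer to ER
than to BA in D; family-membership assertions use networks generated by
the BA model itself.

Default panel: 12 networks, λ ∈ {0, 0.1, …, 1} plus a duplicate at 0.5,
N = 300, target m = 4500 — directed density 0.05, the density of real
~520-TF networks (≈ 14000 edges), because density rather than mean degree
is what the distance-based measures see (see the D limitation above).
Per-network edge counts are jittered uniformly within ±5% of the target:
on a pure one-parameter gradient every monotone feature is collinear with
vulnerability, whereas real tissue panels vary in several directions; the
jitter moves raw connectivity features (density, efficiency, mean degree,
path lengths) without moving the matched-ensemble deviations D_ER/D_BA or
the normalized damage curves, which is precisely the methodological
distinction the panel exists to probe. The truth table (λ and realized m
per network) is emitted next to the data.

The accessibility generator draws negative-binomial counts (dispersion
θ = 5) and converts to TPM. ESC samples draw from a flat expected profile
at baseline × 1.5 (more accessible); Adult samples from an exponentially
decaying profile exp(−c·(1−ε)·u) over the region order with c = 6 and
evenness dial ε (default 0.5; ε = 1 is the null case of equal evenness).
Defaults: 300 regions per class, 8 samples per group — sample sizes in
the range of public ESC/adult DNase-seq panels, counts large enough that
per-sample entropies concentrate. At the defaults the designed ESC−Adult
entropy gap (≈ 0.31 nats) is detected by the rank-sum pipeline in ≥ 95 of
100 seeds. What the generator does *not* emulate: genomic covariates
(GC, mappability), correlated noise between nearby regions, batch
structure, or heavy sample-level library-size artifacts — so passing
tests validate the statistical machinery, not robustness to those
real-data complications.

## Problem sizes and determinism

Simulation-heavy checks run at deliberately scaled sizes: 20-point
removal grids (0.05 steps), 100-replicate error curves, 100-replicate
null ensembles, N = 500/m = 12500 for the ER-vs-BA contrast and
N = 300/m ≈ 4500 for the gradient panel. These keep a full test run plus
the acceptance script in the minutes range on one CPU while leaving every
statistical conclusion comfortably powered; the library defaults (0.01
grid, 1000 error replicates) match the canonical experiment instead.
Every stochastic routine takes an explicit seed; the pipeline derives
per-stage seeds from one base seed via `SeedSequence` spawning and writes
them, with the package version, chosen conventions, input hashes and
stage timings, into `manifest.json`. Two runs from the same config are
byte-identical.

## Known limitations

- The synthetic gradient is one structural axis plus density jitter; with
  12 networks, D_ER, D_BA and degree-sequence entropy — three views of
  the same heterogeneity — predict vulnerability almost equally well, and
  their CV-MSE ordering can swap between panel seeds even though the
  vulnerability–D_ER association itself is always strong.
- D on dense graphs (directed density ≳ 0.1) is poorly resolving; keep
  panels near the real-network density when comparing magnitudes.
- The BA analog matches edge counts only in expectation; z-scores against
  BA ensembles for edge-count-tied features inherit that extra variance.
- Attack simulations implement degree targeting only; betweenness or
  eigenvector targeting and edge percolation are out of scope.
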