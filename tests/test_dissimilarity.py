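import networkx as nx
import numpy as np
import pytest

from netplast import dissimilarity as dsm
from netplast import synthetic
from netplast.null_models import generate_er

from conftest import digraph, random_digraph


def relabel(net, seed):
    rng = np.random.default_rng(seed)
    names = list(net.nodes())
    perm = rng.permutation(len(names))
    mapping = {names[i]: f"r{perm[i]}" for i in range(len(names))}
    out = nx.relabel_nodes(net, mapping)
    out.graph["name"] = net.graph.get("name", "") + "_relab"
    return out


class TestDistanceProfile:
    def test_complete_graph_point_mass_and_zero_nnd(self):
        g = nx.complete_graph(6, create_using=nx.DiGraph)
        prof = dsm.distance_profile(g)
        np.testing.assert_allclose(prof.node_dists[:, 0], 1.0)
        assert prof.nnd == 0.0
        assert prof.diameter == 1

    def test_star_hand_distributions(self):
        # undirected star K1,3: hub at distance 1 from all, leaves see
        # 1/3 at distance 1 and 2/3 at distance 2
        g = digraph([("hub", "a"), ("hub", "b"), ("hub", "c")])
        prof = dsm.distance_profile(g)
        hub = prof.node_dists[0]
        leaf = prof.node_dists[1]
        np.testing.assert_allclose(hub, [1.0, 0.0, 0.0])
        np.testing.assert_allclose(leaf, [1 / 3, 2 / 3, 0.0])
        np.testing.assert_allclose(prof.mu,
                                   [(1 + 3 * (1 / 3)) / 4, 0.5, 0.0])

    def test_isolated_node_mass_in_unreachable_bin(self):
        g = digraph([("a", "b"), ("b", "a")], nodes=["a", "b", "z"])
        prof = dsm.distance_profile(g)
        # every node sees 1/(N-1) of the others as unreachable
        np.testing.assert_allclose(prof.node_dists[:, -1], [0.5, 0.5, 1.0])

    def test_rows_sum_to_one(self):
        g = random_digraph(25, 0.1, seed=3)
        prof = dsm.distance_profile(g)
        np.testing.assert_allclose(prof.node_dists.sum(axis=1), 1.0)
        assert prof.mu.sum() == pytest.approx(1.0)
        assert prof.nnd >= 0


class TestDissimilarity:
    def test_self_dissimilarity_zero(self):
        g = random_digraph(20, 0.2, seed=0)
        assert dsm.dissimilarity(g, g) == 0.0

    @pytest.mark.parametrize("seed", range(6))
    def test_relabeling_invariance(self, seed):
        g = random_digraph(30, 0.15, seed=seed)
        assert dsm.dissimilarity(g, relabel(g, seed)) == pytest.approx(
            0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_symmetry_and_bounds(self, seed):
        g = random_digraph(25, 0.1, seed=seed)
        h = random_digraph(25, 0.3, seed=seed + 100)
        d1 = dsm.dissimilarity(g, h)
        d2 = dsm.dissimilarity(h, g)
        assert d1 == pytest.approx(d2)
        assert 0 <= d1 <= 1

    def test_weights_must_sum_to_one(self):
        g = random_digraph(10, 0.3, seed=1)
        with pytest.raises(ValueError, match="sum to 1"):
            dsm.dissimilarity(g, g, weights=(0.5, 0.5, 0.5))

    def test_reduces_to_first_term_with_alpha_off_and_equal_nnd(self):
        # two relabelings have identical NND, so with the alpha term off
        # D is exactly the first (mu-comparison) term
        g = random_digraph(20, 0.25, seed=2)
        h = random_digraph(20, 0.25, seed=7)
        sa, sb = dsm.graph_signature(g), dsm.graph_signature(h)
        sb.profile.nnd = sa.profile.nnd
        d = dsm.dissimilarity_from_signatures(sa, sb, alpha_term=False)
        mu_a, mu_b = dsm._pad_mu(sa.profile.mu, sb.profile.mu)
        expected = 0.45 * np.sqrt(dsm._jsd_two(mu_a, mu_b) / dsm.LOG2)
        assert d == pytest.approx(expected)

    def test_discriminates_along_heterogeneity_gradient(self):
        g0 = synthetic.mixture_network(100, 1200, 0.0, seed=1)
        g1 = synthetic.mixture_network(100, 1200, 1.0, seed=2)
        er = generate_er(100, 1200, seed=3)
        assert dsm.dissimilarity(er, g1) > dsm.dissimilarity(er, g0)


class TestPairwiseDissimilarity:
    def test_zero_entry_for_isomorphic_pair(self):
        g = random_digraph(15, 0.2, seed=4, name="g")
        h = relabel(g, 1)
        k = random_digraph(15, 0.4, seed=5, name="k")
        matrix, summary, _ = dsm.pairwise_dissimilarity([g, h, k])
        assert matrix.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert matrix.shape == (3, 3)
        np.testing.assert_allclose(matrix.to_numpy(), matrix.to_numpy().T)
        np.testing.assert_allclose(np.diag(matrix.to_numpy()), 0.0)

    def test_homogeneous_outlier_has_largest_median_d(self):
        nets = [synthetic.mixture_network(90, 900, 1.0, seed=s,
                                          name=f"ba{s}") for s in range(4)]
        nets.append(synthetic.mixture_network(90, 900, 0.0, seed=9,
                                              name="er_like"))
        matrix, summary, linkage = dsm.pairwise_dissimilarity(nets)
        assert summary["median_D"].idxmax() == "er_like"

    def test_newick_export_contains_all_names(self):
        nets = [random_digraph(12, 0.3, seed=s, name=f"n{s}")
                for s in range(3)]
        matrix, _, linkage = dsm.pairwise_dissimilarity(nets)
        nwk = dsm.linkage_to_newick(linkage, list(matrix.index))
        assert nwk.endswith(";")
        for name in matrix.index:
            assert name in nwk

    def test_single_network_rejected(self):
        with pytest.raises(ValueError):
            dsm.pairwise_dissimilarity([random_digraph(10, 0.3, seed=0)])


class TestGroupComparison:
    def test_isomorphic_groups_give_p_one(self):
        g = random_digraph(12, 0.3, seed=0, name="a0")
        nets = [g] + [relabel(g, s) for s in (1, 2, 3)]
        for i, n in enumerate(nets):
            n.graph["name"] = f"n{i}"
        matrix, _, _ = dsm.pairwise_dissimilarity(nets)
        labels = {"n0": "A", "n1": "A", "n2": "B", "n3": "B"}
        res = dsm.compare_dissimilarity_groups(matrix, labels)
        assert res["p_value"] == pytest.approx(1.0)

    def test_label_swap_keeps_two_sided_p(self):
        nets = [synthetic.mixture_network(60, 500, lam, seed=s, name=f"n{s}")
                for s, lam in enumerate([0, 0, 1, 1])]
        matrix, _, _ = dsm.pairwise_dissimilarity(nets)
        lab = {"n0": "A", "n1": "A", "n2": "B", "n3": "B"}
        swapped = {k: ("B" if v == "A" else "A") for k, v in lab.items()}
        p1 = dsm.compare_dissimilarity_groups(matrix, lab)["p_value"]
        p2 = dsm.compare_dissimilarity_groups(matrix, swapped)["p_value"]
        assert p1 == pytest.approx(p2)

    def test_small_group_rejected(self):
        nets = [random_digraph(10, 0.3, seed=s, name=f"n{s}")
                for s in range(3)]
        matrix, _, _ = dsm.pairwise_dissimilarity(nets)
        with pytest.raises(ValueError):
            dsm.compare_dissimilarity_groups(
                matrix, {"n0": "A", "n1": "B", "n2": "B"})

    def test_designed_separation_is_detected(self):
        nets = []
        for s in range(4):
            nets.append(synthetic.mixture_network(80, 800, 0.1, seed=s,
                                                  name=f"esc{s}"))
        for s in range(4):
            nets.append(synthetic.mixture_network(80, 800, 1.0, seed=50 + s,
                                                  name=f"adult{s}"))
        matrix, _, _ = dsm.pairwise_dissimilarity(nets)
        labels = {n: ("ESC" if n.startswith("esc") else "Adult")
                  for n in matrix.index}
        res = dsm.compare_dissimilarity_groups(matrix, labels)
        assert res["median_between"] > res["median_within"]
        assert res["p_value"] < 0.05
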