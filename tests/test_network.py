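"""Shrinkage partial correlations, edge orientation, clustering, sweep."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from replicaging import network as net
from replicaging import synthdata as sd


def closed_form_pcor(r_yz, r_yx, r_zx):
    return (r_yz - r_yx * r_zx) / np.sqrt((1 - r_yx**2) * (1 - r_zx**2))


class TestProfileSignalFilter:
    times = sd.DEFAULT_HARVEST_TIMES

    def test_constant_profile_removed(self):
        prof = pd.DataFrame([[3.0] * 12], index=["flat"], columns=self.times)
        kept, scores = net.profile_signal_filter(prof)
        assert scores["flat"] == 0.0
        assert "flat" not in kept.index

    def test_strong_trend_retained(self):
        rng = np.random.default_rng(1)
        u = (self.times - self.times[0]) / (self.times[-1] - self.times[0])
        prof = pd.DataFrame(
            np.outer(np.ones(5), u) + rng.normal(0, 0.01, (5, 12)),
            index=[f"g{i}" for i in range(5)],
            columns=self.times,
        )
        kept, scores = net.profile_signal_filter(prof)
        assert len(kept) == 5
        assert (scores > 10).all()

    def test_white_noise_mostly_removed(self):
        rng = np.random.default_rng(2)
        prof = pd.DataFrame(
            rng.normal(size=(1000, 12)), columns=self.times
        )
        kept, _ = net.profile_signal_filter(prof)
        assert len(kept) <= 50  # >= 95% of pure-noise profiles removed

    def test_too_few_time_points_rejected(self):
        prof = pd.DataFrame([[1.0, 2.0, 3.0]], columns=[1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            net.profile_signal_scores(prof)


class TestShrinkCorrelation:
    def test_orthogonal_profiles_give_identity(self):
        # exactly orthogonal, zero-mean columns -> sample correlations 0
        prof = pd.DataFrame(
            [[1.0, -1.0, 1.0, -1.0], [1.0, 1.0, -1.0, -1.0]], index=["a", "b"]
        )
        R, lam = net.shrink_correlation(prof)
        np.testing.assert_allclose(R.to_numpy(), np.eye(2), atol=1e-12)

    def test_large_n_small_p_shrinkage_vanishes(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=500)
        prof = pd.DataFrame(
            [z + rng.normal(0, 0.5, 500), z + rng.normal(0, 0.5, 500), rng.normal(size=500)]
        )
        R, lam = net.shrink_correlation(prof)
        assert lam < 0.05
        sample = np.corrcoef(prof.to_numpy())
        np.testing.assert_allclose(R.to_numpy(), sample, atol=0.05)

    def test_duplicated_profile_stays_below_one_but_maximal(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=12)
        prof = pd.DataFrame([x, x, rng.normal(size=12)], index=["a", "a2", "b"])
        R, lam = net.shrink_correlation(prof)
        assert R.loc["a", "a2"] < 1.0
        assert R.loc["a", "a2"] == R.loc["a"].drop("a").max()
        # still positive definite
        assert np.linalg.eigvalsh(R.to_numpy()).min() > 0

    def test_zero_variance_gene_excluded(self):
        prof = pd.DataFrame(
            [[1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0], [4.0, 1.0, 3.0, 2.0]],
            index=["flat", "a", "b"],
        )
        R, _ = net.shrink_correlation(prof)
        assert "flat" not in R.index


class TestPartialCorrelationNetwork:
    def test_three_node_fork_closed_form(self):
        # r_xy = r_xz = 0.9, r_yz = 0.81 -> pcor(y,z|x) = 0
        R = pd.DataFrame(
            [[1.0, 0.9, 0.9], [0.9, 1.0, 0.81], [0.9, 0.81, 1.0]],
            index=list("xyz"),
            columns=list("xyz"),
        )
        pcor = net.partial_correlations(R)
        assert pcor.loc["y", "z"] == pytest.approx(0.0, abs=1e-12)
        expected_xy = closed_form_pcor(0.9, 0.9, 0.81)
        assert pcor.loc["x", "y"] == pytest.approx(expected_xy, abs=1e-12)
        G = net.partial_correlation_network(R, cutoff=0.1)
        assert set(map(frozenset, G.edges)) == {frozenset(("x", "y")), frozenset(("x", "z"))}

    def test_random_three_node_closed_form(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            a, b = rng.uniform(-0.7, 0.7, 2)
            c = a * b + rng.uniform(-0.2, 0.2)
            R = pd.DataFrame(
                [[1, a, b], [a, 1, c], [b, c, 1.0]], index=list("xyz"), columns=list("xyz")
            )
            if np.linalg.eigvalsh(R).min() <= 1e-6:
                continue
            pcor = net.partial_correlations(R)
            assert pcor.loc["y", "z"] == pytest.approx(
                closed_form_pcor(c, a, b), abs=1e-12
            )

    def test_identity_has_no_edges(self):
        R = pd.DataFrame(np.eye(4), index=list("abcd"), columns=list("abcd"))
        G = net.partial_correlation_network(R, cutoff=0.01)
        assert G.number_of_edges() == 0

    def test_zero_cutoff_gives_complete_graph(self):
        rng = np.random.default_rng(7)
        prof = pd.DataFrame(rng.normal(size=(5, 30)))
        R, _ = net.shrink_correlation(prof)
        G = net.partial_correlation_network(R, cutoff=0.0)
        assert G.number_of_edges() == 10


class TestOrientation:
    def test_tie_left_undirected(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=20)
        prof = pd.DataFrame([x, x + rng.normal(0, 0.1, 20)], index=["m", "n"])
        G = nx.Graph()
        G.add_edge("m", "n")
        D, spv = net.orient_edges(G, prof)
        # SPV of both endpoints of an isolated pair is identical (1 - r^2)
        assert spv["m"] == pytest.approx(spv["n"], rel=1e-9)
        assert D.number_of_edges() == 0
        assert ("m", "n") in D.graph["undirected_ties"]

    def test_orientation_antisymmetric_in_node_order(self):
        prof, labels, parents = sd.generate_driver_responder(5, 15, seed=9)
        R, _ = net.shrink_correlation(prof)
        G = net.partial_correlation_network(R, 0.05)
        if G.number_of_edges() == 0:
            pytest.skip("no edges at this cutoff")
        D1, _ = net.orient_edges(G, prof.loc[list(G.nodes)])
        H = nx.Graph()
        H.add_nodes_from(reversed(list(G.nodes)))
        H.add_edges_from((v, u, d) for u, v, d in G.edges(data=True))
        D2, _ = net.orient_edges(H, prof.loc[list(H.nodes)])
        assert set(D1.edges) == set(D2.edges)

    def test_planted_chain_orients_driver_to_responders(self):
        """A driver with several lagged responders has the higher SPV."""
        prof, labels, parents = sd.generate_driver_responder(
            2, 8, seed=10, n_parents=1
        )
        driver = "drv0000"
        children = [r for r, ps in parents.items() if ps == [driver]]
        if len(children) < 2:
            pytest.skip("seed gave driver fewer than 2 children")
        G = nx.Graph()
        for c in children:
            G.add_edge(driver, c)
        for a, b in itertools.combinations(children, 2):
            G.add_edge(a, b)
        D, spv = net.orient_edges(G, prof.loc[list(G.nodes)], tolerance=0.5)
        assert spv[driver] > spv[children].max()
        for c in children:
            assert D.has_edge(driver, c)


class TestClusterAndRank:
    def _two_cliques_with_arrows(self):
        D = nx.DiGraph()
        a = [f"a{i}" for i in range(4)]
        b = [f"b{i}" for i in range(4)]
        for u, v in itertools.combinations(a, 2):
            D.add_edge(u, v)
        for u, v in itertools.combinations(b, 2):
            D.add_edge(u, v)
        # 5 arrows A -> B, 1 arrow B -> A
        for i in range(4):
            D.add_edge(a[i], b[i])
        D.add_edge("a0", "b1")
        D.add_edge("b2", "a2")
        return D, a, b

    def test_causal_ratio_direct_count(self):
        D, a, b = self._two_cliques_with_arrows()
        clusters = [frozenset(a), frozenset(b)]
        labels, dm, rank = net.cluster_and_rank(D, clusters)
        assert dm.loc[0, 1] == 5 and dm.loc[1, 0] == 1
        assert rank.loc[0, "causal_ratio"] == pytest.approx(5.0)
        assert rank.loc[1, "causal_ratio"] == pytest.approx(0.2)
        assert rank.index[0] == 0  # driver clique ranked causal

    def test_direction_matrix_counts_sum(self):
        D, a, b = self._two_cliques_with_arrows()
        clusters = [frozenset(a), frozenset(b)]
        _, dm, rank = net.cluster_and_rank(D, clusters)
        inter = dm.loc[0, 1] + dm.loc[1, 0]
        assert rank["outgoing"].sum() == inter
        assert rank["incoming"].sum() == inter

    def test_disconnected_cliques_found_by_modularity(self):
        G = nx.Graph()
        for offset in (0, 4):
            nodes = [f"n{offset + i}" for i in range(4)]
            G.add_edges_from(itertools.combinations(nodes, 2))
        clusters = net.modularity_clusters(G)
        assert sorted(map(len, clusters)) == [4, 4]

    def test_no_intercluster_arrows_ranking_degenerate(self):
        D = nx.DiGraph()
        D.add_edge("a0", "a1")
        D.add_edge("b0", "b1")
        clusters = [frozenset(["a0", "a1"]), frozenset(["b0", "b1"])]
        _, _, rank = net.cluster_and_rank(D, clusters)
        assert rank["causal_ratio"].isna().all()

    def test_modularity_matches_brute_force_on_small_graphs(self):
        graphs = [
            nx.barbell_graph(4, 0),
            nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(4)),
            nx.cycle_graph(6),
        ]
        for G in graphs:
            H = nx.relabel_nodes(G, {n: f"n{n}" for n in G.nodes})
            greedy = net.modularity_clusters(H)
            brute, q_best = net.brute_force_modularity(H)
            from networkx.algorithms.community import modularity

            assert modularity(H, greedy) == pytest.approx(q_best, abs=1e-12)


class TestSensitivitySweep:
    def test_repeated_cutoff_gives_identical_rows_and_stability_one(self):
        prof, _, _ = sd.generate_driver_responder(10, 30, seed=12)
        table, stability, nets = net.sensitivity_sweep(
            prof, [0.04, 0.04], signal_threshold=None
        )
        assert table.iloc[0, 1:].equals(table.iloc[1, 1:])
        assert stability == pytest.approx(1.0)

    def test_edge_count_non_increasing_in_cutoff(self):
        prof, _, _ = sd.generate_driver_responder(20, 60, seed=13)
        table, _, _ = net.sensitivity_sweep(
            prof, [0.02, 0.03, 0.05], signal_threshold=None
        )
        assert np.all(np.diff(table["n_edges"]) <= 0)

    def test_single_cutoff_rejected(self):
        prof, _, _ = sd.generate_driver_responder(5, 10, seed=14)
        with pytest.raises(ValueError):
            net.sensitivity_sweep(prof, [0.05], signal_threshold=None)


@pytest.fixture(scope="module")
def system():
    prof, labels, _ = sd.generate_driver_responder(50, 150, seed=0)
    return prof, labels


class TestBuildNetworkPlanted:
    """Planted driver/responder recovery at the level that is identifiable."""

    @pytest.mark.parametrize("cutoff", net.DEFAULT_CUTOFF_GRID)
    def test_driver_spv_exceeds_responder_spv(self, system, cutoff):
        prof, labels = system
        network = net.build_network(prof, cutoff, signal_threshold=None)
        spv = network.spv
        drivers = [n for n in spv.index if labels[n] == "driver"]
        responders = [n for n in spv.index if labels[n] == "responder"]
        assert drivers and responders
        assert spv[drivers].median() > spv[responders].median()

    @pytest.mark.parametrize("cutoff", net.DEFAULT_CUTOFF_GRID)
    def test_arrows_flow_from_drivers_to_responders(self, system, cutoff):
        prof, labels = system
        network = net.build_network(prof, cutoff, signal_threshold=None)
        d_to_r = r_to_d = 0
        for u, v in network.directed.edges:
            if labels[u] == "driver" and labels[v] == "responder":
                d_to_r += 1
            elif labels[u] == "responder" and labels[v] == "driver":
                r_to_d += 1
        assert d_to_r > r_to_d
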