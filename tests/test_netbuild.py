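import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
import scipy.stats

from cavenet import netbuild
from cavenet.tables import FeatureTable


def _table(rows, sample_n=None):
    rows = np.asarray(rows)
    return FeatureTable(
        [f"f{i}" for i in range(rows.shape[0])],
        [f"s{j}" for j in range(rows.shape[1])],
        rows,
    )


class TestPairwiseSpearman:
    def test_comonotone_pair(self):
        t = _table([[1, 2, 3, 4, 5], [10, 20, 30, 40, 50], [5, 4, 3, 2, 1]])
        s = netbuild.pairwise_spearman(t)
        lookup = {
            frozenset((r.feature_a, r.feature_b)): r.rho for r in s.pairs.itertuples()
        }
        assert lookup[frozenset(("f0", "f1"))] == pytest.approx(1.0)
        assert lookup[frozenset(("f0", "f2"))] == pytest.approx(-1.0)

    def test_rank_then_pearson_oracle(self):
        t = _table([[1, 2, 3, 5], [3, 1, 2, 4], [9, 2, 1, 1]])
        s = netbuild.pairwise_spearman(t)
        for r in s.pairs.itertuples():
            i = int(r.feature_a[1:])
            j = int(r.feature_b[1:])
            rx = scipy.stats.rankdata(t.counts[i])
            ry = scipy.stats.rankdata(t.counts[j])
            assert r.rho == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-12)

    def test_constant_feature_excluded(self):
        t = _table([[1, 2, 3, 4], [7, 7, 7, 7], [4, 3, 2, 1]])
        s = netbuild.pairwise_spearman(t)
        assert s.excluded == ["f1"]
        names = set(s.pairs["feature_a"]) | set(s.pairs["feature_b"])
        assert "f1" not in names

    def test_q_at_least_p(self):
        rng = np.random.default_rng(0)
        t = _table(rng.integers(0, 50, size=(8, 10)))
        s = netbuild.pairwise_spearman(t)
        assert (s.pairs["q"] >= s.pairs["p"] - 1e-12).all()

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            netbuild.pairwise_spearman(_table([[1, 2, 3], [3, 2, 1]]))


class TestBenjaminiHochberg:
    def test_step_up_hand_computation(self):
        # classic worked example: m=4 sorted p-values
        from statsmodels.stats.multitest import multipletests

        q = multipletests([0.005, 0.01, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(q, [0.02, 0.02, 0.04, 0.04])

    def test_q_monotone_in_sorted_p(self):
        rng = np.random.default_rng(1)
        t = _table(rng.integers(0, 30, size=(10, 8)))
        s = netbuild.pairwise_spearman(t)
        df = s.pairs.sort_values("p")
        assert (np.diff(df["q"].to_numpy()) >= -1e-12).all()


def _screen(rows):
    df = pd.DataFrame(rows, columns=["feature_a", "feature_b", "rho", "p", "q"])
    return netbuild.CorrelationScreen(pairs=df, n_samples=10)


class TestBuildNetwork:
    def test_boundary_rho_excluded(self):
        s = _screen([("a", "b", 0.69, 0.0001, 0.001), ("a", "c", 0.70, 0.0001, 0.001)])
        g = netbuild.build_network(s, rho_min=0.7, alpha=0.05)
        assert not g.has_edge("a", "b")
        assert g.has_edge("a", "c")

    def test_negative_edge_kept_with_sign(self):
        s = _screen([("a", "b", -0.8, 0.001, 0.01)])
        g = netbuild.build_network(s, rho_min=0.7, alpha=0.05)
        assert g["a"]["b"]["sign"] == "-"
        assert g["a"]["b"]["weight"] == pytest.approx(-0.8)
        assert g["a"]["b"]["abs_weight"] == pytest.approx(0.8)

    def test_toy_screen_matches_exhaustive_thresholding(self):
        rows = [
            ("a", "b", 0.9, 1e-4, 1e-3),
            ("a", "c", 0.75, 0.01, 0.06),  # q too high
            ("b", "c", -0.71, 0.001, 0.01),
            ("c", "d", 0.5, 0.2, 0.3),  # rho too low
            ("a", "d", 0.95, 0.03, 0.049),
        ]
        g = netbuild.build_network(_screen(rows), rho_min=0.7, alpha=0.05)
        expected = {
            frozenset((a, b))
            for a, b, rho, p, q in rows
            if abs(rho) >= 0.7 and q < 0.05
        }
        assert {frozenset(e) for e in g.edges} == expected
        # isolated candidates (only in failing pairs) never become nodes
        assert set(g.nodes) == set(itertools.chain.from_iterable(expected))

    def test_empty_edge_set_diagnostic(self):
        s = _screen([("a", "b", 0.3, 0.5, 0.6)])
        with pytest.raises(ValueError, match="no edge"):
            netbuild.build_network(s, rho_min=0.7, alpha=0.05)

    def test_raw_p_option(self):
        s = _screen([("a", "b", 0.9, 0.01, 0.2)])
        with pytest.raises(ValueError):
            netbuild.build_network(s, rho_min=0.7, alpha=0.05)
        g = netbuild.build_network(s, rho_min=0.7, alpha=0.05, use_raw_p=True)
        assert g.has_edge("a", "b")


def _bruteforce_apl_diam(g):
    # Floyd-Warshall over connected pairs
    nodes = list(g.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0)
    for u, v in g.edges:
        dist[idx[u], idx[v]] = dist[idx[v], idx[u]] = 1
    for k in range(n):
        dist = np.minimum(dist, dist[:, k : k + 1] + dist[k : k + 1, :])
    finite = dist[np.isfinite(dist) & (dist > 0)]
    apl = finite.mean() if finite.size else 0.0
    diam = finite.max() if finite.size else 0
    return apl, int(diam)


def _bruteforce_acc(g):
    # local clustering by triangle enumeration; degree<2 contributes 0
    vals = []
    for v in g.nodes:
        nbrs = list(g[v])
        k = len(nbrs)
        if k < 2:
            vals.append(0.0)
            continue
        links = sum(1 for a, b in itertools.combinations(nbrs, 2) if g.has_edge(a, b))
        vals.append(2 * links / (k * (k - 1)))
    return float(np.mean(vals))


class TestTopology:
    def test_triangle(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c")])
        topo = netbuild.topology(g, seed=0)
        assert topo.acc == pytest.approx(1.0)
        assert topo.apl == pytest.approx(1.0)
        assert topo.diameter == 1
        assert topo.density == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_random_graphs_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        g = nx.gnp_random_graph(n, 0.35, seed=seed)
        g.add_edge(0, 1)  # at least one edge
        topo = netbuild.topology(g, seed=0)
        apl, diam = _bruteforce_apl_diam(g)
        assert topo.apl == pytest.approx(apl)
        assert topo.diameter == diam
        assert topo.acc == pytest.approx(_bruteforce_acc(g))
        e, n_nodes = g.number_of_edges(), g.number_of_nodes()
        assert topo.density == pytest.approx(2 * e / (n_nodes * (n_nodes - 1)))
        assert topo.avg_degree == pytest.approx(2 * e / n_nodes)

    def test_disconnected_graph_uses_connected_pairs(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("c", "d"), ("d", "e")])
        topo = netbuild.topology(g, seed=0)
        # pairs: a-b (1), c-d (1), d-e (1), c-e (2)
        assert topo.apl == pytest.approx((1 + 1 + 1 + 2) / 4)
        assert topo.diameter == 2

    def test_weighted_degree_uses_abs_rho(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=-0.8, abs_weight=0.8, sign="-")
        g.add_edge("b", "c", weight=0.9, abs_weight=0.9, sign="+")
        topo = netbuild.topology(g, seed=0)
        assert topo.avg_weighted_degree == pytest.approx((0.8 + 1.7 + 0.9) / 3)
        assert topo.positive_edge_fraction == pytest.approx(0.5)


class TestModules:
    def test_two_disjoint_triangles_closed_form(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        partition, q = netbuild.detect_modules(g, seed=0)
        assert sorted(sorted(c) for c in partition) == [[0, 1, 2], [3, 4, 5]]
        assert q == pytest.approx(0.5)

    def test_single_clique_one_module_q_zero(self):
        g = nx.complete_graph(5)
        partition, q = netbuild.detect_modules(g, seed=0)
        assert len(partition) == 1
        assert q == pytest.approx(0.0)

    def test_partition_beats_trivial_partitions(self):
        rng = np.random.default_rng(7)
        g = nx.gnp_random_graph(15, 0.3, seed=11)
        g.add_edge(0, 1)
        partition, q = netbuild.detect_modules(g, seed=0)
        singletons = [{v} for v in g.nodes]
        one = [set(g.nodes)]
        assert q >= netbuild.modularity(g, singletons) - 1e-12
        assert q >= netbuild.modularity(g, one) - 1e-12

    def test_seed_determinism(self):
        g = nx.gnp_random_graph(25, 0.2, seed=3)
        p1, q1 = netbuild.detect_modules(g, seed=4)
        p2, q2 = netbuild.detect_modules(g, seed=4)
        assert p1 == p2 and q1 == q2


class TestModuleCensus:
    def test_large_module_boundary_strict(self):
        g = nx.empty_graph(200)
        partition = [set(range(10)), set(range(10, 21)), set(range(21, 200))]
        census = netbuild.module_census(partition, g, large_frac=0.05)
        assert not census.loc[0, "large"]  # 10/200 = 5.0%, not over 5%
        assert census.loc[1, "large"]  # 11/200 = 5.5%
        assert census["size"].sum() == 200

    def test_partition_must_cover(self):
        g = nx.path_graph(4)
        with pytest.raises(ValueError):
            netbuild.module_census([{0, 1}], g)


def test_exports_round_trip(tmp_path):
    g = nx.Graph()
    g.add_edge("a", "b", weight=0.9, abs_weight=0.9, sign="+", q=0.001)
    g.add_edge("b", "c", weight=-0.75, abs_weight=0.75, sign="-", q=0.01)
    netbuild.write_edge_list(g, tmp_path / "edges.csv")
    df = pd.read_csv(tmp_path / "edges.csv")
    assert list(df.columns) == ["Source", "Target", "Weight", "Sign"]
    assert set(df["Sign"]) == {"+", "-"}
    assert (df["Weight"] > 0).all()
    netbuild.write_graphml(g, tmp_path / "net.graphml", partition=[{"a", "b"}, {"c"}])
    back = nx.read_graphml(tmp_path / "net.graphml")
    assert back.nodes["a"]["module"] != back.nodes["c"]["module"]
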