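import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cavenet import netroles
from cavenet.tables import TaxonomyMap


@pytest.fixture
def toy_graph():
    """8 nodes, two hand-assigned modules with an uneven hub."""
    g = nx.Graph()
    g.add_edges_from(
        [
            (0, 1), (0, 2), (0, 3), (1, 2),  # module A: 0..3, 0 is the hub
            (4, 5), (5, 6), (6, 7),          # module B: 4..7, a path
            (3, 4),                           # one bridge
        ]
    )
    partition = [{0, 1, 2, 3}, {4, 5, 6, 7}]
    return g, partition


def _zi_oracle(node, partition, g):
    owner = {v: m for m, mem in enumerate(partition) for v in mem}
    within = lambda v: sum(1 for u in g[v] if owner[u] == owner[v])
    module = [v for v in g.nodes if owner[v] == owner[node]]
    ks = np.array([within(v) for v in module], dtype=float)
    return 0.0 if ks.std() == 0 else (within(node) - ks.mean()) / ks.std()


def _pi_oracle(node, partition, g):
    owner = {v: m for m, mem in enumerate(partition) for v in mem}
    k = g.degree(node)
    tally = {}
    for u in g[node]:
        tally[owner[u]] = tally.get(owner[u], 0) + 1
    return 1.0 - sum((c / k) ** 2 for c in tally.values())


class TestZi:
    def test_mean_within_degree_gives_zero(self):
        # all nodes of a triangle have within-degree 2 -> sd 0 -> Zi 0
        g = nx.complete_graph(3)
        assert netroles.zi(0, [{0, 1, 2}], g) == 0.0

    def test_singleton_module_is_zero(self):
        g = nx.path_graph(3)
        assert netroles.zi(2, [{0, 1}, {2}], g) == 0.0

    def test_toy_graph_matches_formula_oracle(self, toy_graph):
        g, partition = toy_graph
        for v in g.nodes:
            assert netroles.zi(v, partition, g) == pytest.approx(
                _zi_oracle(v, partition, g)
            )

    def test_zi_mean_zero_within_modules(self, toy_graph):
        g, partition = toy_graph
        for module in partition:
            zs = [netroles.zi(v, partition, g) for v in module]
            assert np.mean(zs) == pytest.approx(0.0, abs=1e-12)


class TestPi:
    def test_all_edges_within_module(self):
        g = nx.complete_graph(4)
        assert netroles.pi(0, [{0, 1, 2, 3}], g) == 0.0

    def test_even_two_way_split(self):
        g = nx.star_graph(4)  # center 0, leaves 1..4
        partition = [{0, 1, 2}, {3, 4}]
        assert netroles.pi(0, partition, g) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(4))
    def test_random_graphs_match_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(10, 0.4, seed=seed)
        g.add_edges_from([(0, 1), (2, 3)])
        nodes = list(g.nodes)
        rng.shuffle(nodes)
        partition = [set(nodes[:3]), set(nodes[3:6]), set(nodes[6:])]
        for v in g.nodes:
            if g.degree(v) == 0:
                continue
            assert netroles.pi(v, partition, g) == pytest.approx(
                _pi_oracle(v, partition, g)
            )
            assert 0 <= netroles.pi(v, partition, g) < 1


class TestClassifyRoles:
    @pytest.mark.parametrize(
        "zi,pi,role",
        [
            (2.5, 0.62, "peripheral"),  # both boundaries inclusive-below
            (3.0, 0.7, "network_hub"),
            (0.0, 0.63, "connector"),
            (2.6, 0.62, "module_hub"),
            (-1.0, 0.0, "peripheral"),
        ],
    )
    def test_quoted_boundaries(self, zi, pi, role):
        df = pd.DataFrame({"Zi": [zi], "Pi": [pi]}, index=["n"])
        out = netroles.classify_roles(df)
        assert out.loc["n", "role"] == role
        assert out.loc["n", "keystone"] == (role != "peripheral")

    def test_role_counts_sum_and_relabel_invariance(self, toy_graph):
        g, partition = toy_graph
        roles = netroles.node_role_table(g, partition)
        assert roles["role"].value_counts().sum() == g.number_of_nodes()
        pct = netroles.role_percentages(roles)
        assert pct.sum() == pytest.approx(100.0, abs=0.05)
        # relabel every node: classification is carried by structure only
        mapping = {v: f"x{v}" for v in g.nodes}
        g2 = nx.relabel_nodes(g, mapping)
        part2 = [{mapping[v] for v in mod} for mod in partition]
        roles2 = netroles.node_role_table(g2, part2)
        for v in g.nodes:
            assert roles.loc[v, "role"] == roles2.loc[mapping[v], "role"]

    def test_table_matches_per_node_functions(self, toy_graph):
        g, partition = toy_graph
        roles = netroles.node_role_table(g, partition)
        for v in g.nodes:
            assert roles.loc[v, "Zi"] == pytest.approx(netroles.zi(v, partition, g))
            assert roles.loc[v, "Pi"] == pytest.approx(netroles.pi(v, partition, g))


class TestKeystoneSummary:
    def _roles(self, labels, keystone):
        return pd.DataFrame(
            {
                "taxonomy": labels,
                "keystone": keystone,
                "role": ["connector" if k else "peripheral" for k in keystone],
            },
            index=[f"n{i}" for i in range(len(labels))],
        )

    def test_thirty_two_of_forty_three(self):
        labels = ["USCgamma"] * 32 + ["other"] * 11 + ["bg"] * 5
        keystone = [True] * 43 + [False] * 5
        out = netroles.keystone_summary(self._roles(labels, keystone))
        assert out.loc["USCgamma", "count"] == 32
        assert out.loc["USCgamma", "share_pct"] == pytest.approx(74.42)

    def test_single_taxon_is_100(self):
        out = netroles.keystone_summary(self._roles(["a", "a"], [True, True]))
        assert out.loc["a", "share_pct"] == 100.0

    def test_shares_sum_to_100(self):
        rng = np.random.default_rng(0)
        labels = rng.choice(list("abcd"), size=30).tolist()
        keystone = rng.random(30) < 0.5
        out = netroles.keystone_summary(self._roles(labels, keystone.tolist()))
        assert out["share_pct"].sum() == pytest.approx(100.0, abs=0.05)

    def test_zero_keystones_warns_empty(self):
        with pytest.warns(UserWarning):
            out = netroles.keystone_summary(self._roles(["a"], [False]))
        assert out.empty


class TestKeystoneSubnetwork:
    def _setup(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (0, 2), (0, 3), (4, 5), (5, 6), (6, 7), (8, 9)])
        roles = pd.DataFrame(
            {
                "taxonomy": ["focal"] + ["bg"] * 9,
                "keystone": [True] + [False] * 9,
            },
            index=list(range(10)),
        )
        return g, roles

    def test_focal_plus_neighbors(self):
        g, roles = self._setup()
        sub = netroles.keystone_subnetwork(g, roles, ["focal"])
        assert set(sub.nodes) == {0, 1, 2, 3}

    def test_focal_everything_is_identity(self):
        g = nx.complete_graph(4)
        roles = pd.DataFrame(
            {"taxonomy": ["t"] * 4, "keystone": [True] * 4}, index=list(g.nodes)
        )
        sub = netroles.keystone_subnetwork(g, roles, ["t"])
        assert set(sub.nodes) == set(g.nodes)
        assert set(sub.edges) == set(g.edges)

    def test_matches_bruteforce_neighborhood_union(self):
        g = nx.gnp_random_graph(12, 0.3, seed=5)
        g.add_edge(0, 1)
        roles = pd.DataFrame(
            {
                "taxonomy": ["focal" if v % 4 == 0 else "bg" for v in g.nodes],
                "keystone": [v % 2 == 0 for v in g.nodes],
            },
            index=list(g.nodes),
        )
        focal = [v for v in g.nodes if v % 4 == 0 and v % 2 == 0]
        expected = set(focal) | set(
            itertools.chain.from_iterable(g[v] for v in focal)
        )
        sub = netroles.keystone_subnetwork(g, roles, ["focal"])
        assert set(sub.nodes) == expected

    def test_missing_focal_label_error(self):
        g, roles = self._setup()
        with pytest.raises(ValueError):
            netroles.keystone_subnetwork(g, roles, ["absent"])
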