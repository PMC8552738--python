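"""Signed co-occurrence network construction and topology.

All unordered feature pairs of a filtered table are scored with Spearman's
rank correlation; p-values are Benjamini-Hochberg adjusted over the whole
screen, and an undirected signed graph keeps the pairs with |rho| at or
above the strength threshold and adjusted q below alpha.  Topological
properties mirror the standard co-occurrence network report: node and edge
counts, average path length (APL), average clustering coefficient (ACC),
diameter, modularity, density, average degree (AD), average weighted degree
(AWD), and the positive-edge fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .tables import FeatureTable, TaxonomyMap

__all__ = [
    "CorrelationScreen",
    "pairwise_spearman",
    "build_network",
    "TopologySummary",
    "topology",
    "average_degree_from_counts",
    "density_from_counts",
    "detect_modules",
    "modularity",
    "module_census",
    "write_edge_list",
    "write_graphml",
]


@dataclass
class CorrelationScreen:
    """All unordered feature pairs with rho, raw p, and BH-adjusted q."""

    pairs: pd.DataFrame  # columns: feature_a, feature_b, rho, p, q
    n_samples: int
    excluded: list[str] = field(default_factory=list)  # constant features

    def __len__(self) -> int:
        return len(self.pairs)


def pairwise_spearman(t: FeatureTable) -> CorrelationScreen:
    """Spearman rho and two-sided p for every unordered feature pair.

    Mid-rank (tie-aware) correlations with the t-distribution approximation
    for p; q is the Benjamini-Hochberg adjustment over all pairs jointly.
    Constant features have undefined correlations and are excluded from the
    screen (and recorded).
    """
    if t.n_samples < 4:
        raise ValueError("need at least 4 samples for a correlation screen")
    const = [f for f, row in zip(t.feature_ids, t.counts) if np.ptp(row) == 0]
    keep = [f for f in t.feature_ids if f not in set(const)]
    if len(keep) < 2:
        raise ValueError("fewer than 2 non-constant features; no pairs to screen")
    sub = t.select_features(keep)
    rho, p = scipy.stats.spearmanr(sub.counts, axis=1)
    if np.ndim(rho) == 0:  # scipy collapses the 2-feature case to a scalar
        rho = np.array([[1.0, rho], [rho, 1.0]])
        p = np.array([[0.0, p], [p, 0.0]])
    iu = np.triu_indices(len(keep), k=1)
    pairs = pd.DataFrame(
        {
            "feature_a": np.asarray(keep, dtype=object)[iu[0]],
            "feature_b": np.asarray(keep, dtype=object)[iu[1]],
            "rho": rho[iu],
            "p": p[iu],
        }
    )
    pairs["q"] = multipletests(pairs["p"].to_numpy(), method="fdr_bh")[1]
    return CorrelationScreen(pairs=pairs, n_samples=t.n_samples, excluded=const)


def build_network(
    s: CorrelationScreen,
    rho_min: float = 0.7,
    alpha: float = 0.05,
    taxonomy: TaxonomyMap | None = None,
    use_raw_p: bool = False,
) -> nx.Graph:
    """Threshold a correlation screen into a signed undirected graph.

    An edge is kept iff |rho| >= rho_min and (adjusted) q < alpha; the
    strength threshold is sign-blind and the sign is stored as an edge
    attribute.  Nodes are edge endpoints only, so features whose every
    correlation fell below threshold do not appear.
    """
    if not 0 <= rho_min <= 1:
        raise ValueError(f"rho_min must be in [0, 1], got {rho_min}")
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    pcol = "p" if use_raw_p else "q"
    hits = s.pairs[(s.pairs["rho"].abs() >= rho_min) & (s.pairs[pcol] < alpha)]
    if hits.empty:
        near = s.pairs.assign(strength=s.pairs["rho"].abs()).nlargest(5, "strength")
        diag = "; ".join(
            f"{r.feature_a}-{r.feature_b}: rho={r.rho:.3f}, q={r.q:.3g}"
            for r in near.itertuples()
        )
        raise ValueError(f"no edge passes the thresholds; strongest pairs: {diag}")
    g = nx.Graph()
    for row in hits.itertuples():
        g.add_edge(
            row.feature_a,
            row.feature_b,
            weight=float(row.rho),
            abs_weight=abs(float(row.rho)),
            sign="+" if row.rho > 0 else "-",
            q=float(row.q),
        )
    if taxonomy is not None:
        for node in g.nodes:
            g.nodes[node]["taxonomy"] = taxonomy.label(node)
    return g


@dataclass
class TopologySummary:
    nodes: int
    edges: int
    apl: float
    acc: float
    diameter: int
    modularity: float
    density: float
    avg_degree: float
    avg_weighted_degree: float
    positive_edge_fraction: float
    n_modules: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Nodes": [self.nodes],
                "Edges": [self.edges],
                "APL": [self.apl],
                "ACC": [self.acc],
                "Diam": [self.diameter],
                "Modularity": [self.modularity],
                "Density": [self.density],
                "AD": [self.avg_degree],
                "AWD": [self.avg_weighted_degree],
                "PositiveEdgeFraction": [self.positive_edge_fraction],
                "Modules": [self.n_modules],
            }
        )


def average_degree_from_counts(n_nodes: int, n_edges: int) -> float:
    """AD = 2E/N, the arithmetic identity linking the printed counts."""
    return 2.0 * n_edges / n_nodes


def density_from_counts(n_nodes: int, n_edges: int) -> float:
    """density = 2E / (N (N-1))."""
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def _path_stats(g: nx.Graph) -> tuple[float, int]:
    """APL over connected pairs and diameter as max finite eccentricity.

    Threshold graphs are often disconnected; unreachable pairs are simply
    not averaged and infinite eccentricities are ignored.
    """
    total = 0
    npairs = 0
    diam = 0
    for source, lengths in nx.all_pairs_shortest_path_length(g):
        ecc = 0
        for target, dist in lengths.items():
            if target == source:
                continue
            total += dist
            npairs += 1
            ecc = max(ecc, dist)
        diam = max(diam, ecc)
    apl = total / npairs if npairs else 0.0
    return apl, diam


def topology(
    net: nx.Graph,
    partition: list[set] | None = None,
    seed: int = 0,
) -> TopologySummary:
    """Compute the full topology summary of a signed co-occurrence graph."""
    n, e = net.number_of_nodes(), net.number_of_edges()
    if n < 2:
        raise ValueError("topology needs at least 2 nodes")
    if partition is None:
        partition, q = detect_modules(net, seed=seed)
    else:
        q = modularity(net, partition)
    apl, diam = _path_stats(net)
    weighted_degrees = [
        sum(d.get("abs_weight", abs(d.get("weight", 1.0))) for d in net[v].values())
        for v in net.nodes
    ]
    positives = sum(1 for _, _, d in net.edges(data=True) if d.get("sign", "+") == "+")
    return TopologySummary(
        nodes=n,
        edges=e,
        apl=apl,
        acc=nx.average_clustering(net),  # degree<2 nodes count as 0
        diameter=diam,
        modularity=q,
        density=density_from_counts(n, e),
        avg_degree=average_degree_from_counts(n, e),
        avg_weighted_degree=float(np.mean(weighted_degrees)),
        positive_edge_fraction=positives / e,
        n_modules=len(partition),
    )


def _abs_weighted(net: nx.Graph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    for u, v, d in net.edges(data=True):
        g.add_edge(u, v, weight=d.get("abs_weight", abs(d.get("weight", 1.0))))
    return g


def detect_modules(net: nx.Graph, seed: int = 0) -> tuple[list[set], float]:
    """Greedy (Louvain) modularity maximization on the |rho|-weighted graph.

    Returns the partition as a list of node sets, ordered by decreasing size
    with node-id tie-breaking so a fixed seed gives a fixed output, plus its
    modularity Q.
    """
    if net.number_of_edges() < 1:
        raise ValueError("module detection needs at least one edge")
    g = _abs_weighted(net)
    parts = nx.community.louvain_communities(g, weight="weight", seed=seed)
    parts = sorted(parts, key=lambda c: (-len(c), min(str(v) for v in c)))
    return [set(c) for c in parts], modularity(net, parts)


def modularity(net: nx.Graph, partition) -> float:
    """Newman modularity Q of a partition on the |rho|-weighted graph."""
    return float(
        nx.community.modularity(_abs_weighted(net), partition, weight="weight")
    )


def module_census(
    partition: list[set],
    net: nx.Graph,
    large_frac: float = 0.05,
) -> pd.DataFrame:
    """Module sizes with large-module flags (size/N strictly above large_frac)."""
    covered = set().union(*partition) if partition else set()
    if covered != set(net.nodes):
        raise ValueError("partition does not cover the node set")
    n = net.number_of_nodes()
    rows = []
    for mid, members in enumerate(partition):
        size = len(members)
        rows.append(
            {
                "module": mid,
                "size": size,
                "fraction": size / n,
                "large": size / n > large_frac,
            }
        )
    df = pd.DataFrame(rows).set_index("module")
    assert df["size"].sum() == n
    return df


def write_edge_list(net: nx.Graph, path) -> None:
    """Gephi-loadable edge CSV: Source, Target, Weight, Sign."""
    rows = [
        {
            "Source": u,
            "Target": v,
            "Weight": d.get("abs_weight", abs(d.get("weight", 1.0))),
            "Sign": d.get("sign", "+"),
        }
        for u, v, d in net.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["Source", "Target", "Weight", "Sign"]).to_csv(
        path, index=False
    )


def write_graphml(net: nx.Graph, path, partition: list[set] | None = None) -> None:
    g = net.copy()
    if partition is not None:
        for mid, members in enumerate(partition):
            for v in members:
                g.nodes[v]["module"] = mid
    nx.write_graphml(g, path)
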