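"""Zi-Pi node roles and keystone taxa.

Within-module connectivity Zi is the z-score of a node's degree inside its
own module; among-module connectivity Pi (the participation coefficient) is
one minus the sum of squared per-module edge fractions.  Nodes are
classified with the standard thresholds:

* peripheral:  Zi <= 2.5 and Pi <= 0.62
* connector:   Zi <= 2.5 and Pi >  0.62
* module hub:  Zi >  2.5 and Pi <= 0.62
* network hub: Zi >  2.5 and Pi >  0.62

Connectors, module hubs, and network hubs are keystone taxa.  Both scores
use the unweighted graph (plain degree counts), following the original
role-cartography definition.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .tables import TaxonomyMap

__all__ = [
    "zi",
    "pi",
    "node_role_table",
    "classify_roles",
    "role_percentages",
    "keystone_summary",
    "keystone_subnetwork",
    "ROLES",
]

ROLES = ("peripheral", "connector", "module_hub", "network_hub")
KEYSTONE_ROLES = frozenset({"connector", "module_hub", "network_hub"})


def _module_of(partition: list[set]) -> dict:
    owner = {}
    for mid, members in enumerate(partition):
        for v in members:
            if v in owner:
                raise ValueError(f"node {v!r} appears in more than one module")
            owner[v] = mid
    return owner


def _within_degrees(net: nx.Graph, partition: list[set]) -> dict:
    owner = _module_of(partition)
    return {
        v: sum(1 for u in net[v] if owner[u] == owner[v]) for v in net.nodes
    }


def zi(node, partition: list[set], net: nx.Graph) -> float:
    """Within-module degree z-score of ``node``.

    Zi = (k_is - mean k_js over module s) / sd over module s, where k_is is
    the number of edges from the node into its own module.  Modules with
    zero degree variance (including singletons) give Zi = 0, keeping such
    nodes peripheral unless Pi promotes them.
    """
    owner = _module_of(partition)
    if node not in owner:
        raise ValueError(f"node {node!r} not in partition")
    within = _within_degrees(net, partition)
    module = [v for v in net.nodes if owner[v] == owner[node]]
    ks = np.array([within[v] for v in module], dtype=float)
    sd = ks.std()
    if sd == 0:
        return 0.0
    return float((within[node] - ks.mean()) / sd)


def pi(node, partition: list[set], net: nx.Graph) -> float:
    """Participation coefficient: Pi = 1 - sum_s (k_is / k_i)^2."""
    owner = _module_of(partition)
    k = net.degree(node)
    if k < 1:
        raise ValueError(f"node {node!r} has degree 0; Pi undefined")
    per_module: dict[int, int] = {}
    for u in net[node]:
        per_module[owner[u]] = per_module.get(owner[u], 0) + 1
    return float(1.0 - sum((ks / k) ** 2 for ks in per_module.values()))


def node_role_table(
    net: nx.Graph,
    partition: list[set],
    taxonomy: TaxonomyMap | None = None,
    zi_thr: float = 2.5,
    pi_thr: float = 0.62,
) -> pd.DataFrame:
    """Per-node Zi, Pi, role class, and keystone flag.

    Vectorized over modules so it stays fast on thousand-node graphs; the
    per-node functions :func:`zi` and :func:`pi` are the reference forms.
    """
    owner = _module_of(partition)
    missing = set(net.nodes) - set(owner)
    if missing:
        raise ValueError(f"nodes outside the partition: {sorted(missing)[:5]}")
    within = _within_degrees(net, partition)
    stats = {}
    for mid, members in enumerate(partition):
        ks = np.array([within[v] for v in members], dtype=float)
        stats[mid] = (ks.mean(), ks.std())
    rows = []
    for v in net.nodes:
        mean, sd = stats[owner[v]]
        z = 0.0 if sd == 0 else (within[v] - mean) / sd
        k = net.degree(v)
        per_module: dict[int, int] = {}
        for u in net[v]:
            per_module[owner[u]] = per_module.get(owner[u], 0) + 1
        p = 1.0 - sum((ks / k) ** 2 for ks in per_module.values())
        rows.append(
            {
                "node": v,
                "module": owner[v],
                "within_degree": within[v],
                "degree": k,
                "Zi": z,
                "Pi": p,
                "taxonomy": taxonomy.label(v) if taxonomy is not None else "",
            }
        )
    df = pd.DataFrame(rows).set_index("node")
    return classify_roles(df, zi_thr=zi_thr, pi_thr=pi_thr)


def classify_roles(
    roles: pd.DataFrame,
    zi_thr: float = 2.5,
    pi_thr: float = 0.62,
) -> pd.DataFrame:
    """Assign the four-way role class from Zi and Pi (boundaries inclusive-below)."""
    if not (np.isfinite(zi_thr) and np.isfinite(pi_thr)):
        raise ValueError("thresholds must be finite")
    df = roles.copy()
    low_z = df["Zi"] <= zi_thr
    low_p = df["Pi"] <= pi_thr
    role = np.where(
        low_z,
        np.where(low_p, "peripheral", "connector"),
        np.where(low_p, "module_hub", "network_hub"),
    )
    df["role"] = role
    df["keystone"] = df["role"].isin(KEYSTONE_ROLES)
    return df


def role_percentages(roles: pd.DataFrame) -> pd.Series:
    """Percent of nodes in each role class, to 2 decimals; sums to ~100."""
    counts = roles["role"].value_counts().reindex(ROLES, fill_value=0)
    return (100.0 * counts / len(roles)).round(2)


def keystone_summary(
    roles: pd.DataFrame,
    taxonomy: TaxonomyMap | None = None,
) -> pd.DataFrame:
    """Keystone node counts and percentage shares per taxonomy label."""
    key = roles[roles["keystone"]]
    if key.empty:
        warnings.warn("no keystone nodes in the role table", stacklevel=2)
        return pd.DataFrame(columns=["count", "share_pct"])
    if taxonomy is not None:
        labels = pd.Series({v: taxonomy.label(v) for v in key.index})
    else:
        labels = key["taxonomy"]
    counts = labels.groupby(labels).size().sort_values(ascending=False)
    out = pd.DataFrame(
        {"count": counts, "share_pct": (100.0 * counts / counts.sum()).round(2)}
    )
    out.index.name = "taxon"
    return out


def keystone_subnetwork(
    net: nx.Graph,
    roles: pd.DataFrame,
    focal_labels: list[str],
) -> nx.Graph:
    """Induced subgraph on focal keystone nodes plus their first neighbors."""
    key = roles[roles["keystone"]]
    focal = [v for v in key.index if key.loc[v, "taxonomy"] in set(focal_labels)]
    if not focal:
        raise ValueError(f"no keystone node carries a focal label in {focal_labels}")
    nodes = set(focal)
    for v in focal:
        nodes.update(net[v])
    return net.subgraph(nodes).copy()
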