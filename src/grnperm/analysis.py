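"""Topology statistics and community structure of the final network.

Degree tables rank candidate hub regulators; Louvain community detection on
the undirected projection (edge weight = importance, antiparallel weights
summed) extracts gene modules; module expression profiles average the
mean-scaled profiles of member genes.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import CommunityPartition, CountMatrix, TestedNetwork

__all__ = [
    "degree_statistics",
    "detect_communities",
    "module_profiles",
    "to_graph",
]


def _final_edges(net: TestedNetwork) -> pd.DataFrame:
    edges = net.final_edges
    if len(edges) == 0:
        raise ValueError("network has no edges")
    return edges


def degree_statistics(net: TestedNetwork) -> pd.DataFrame:
    """Per-node in/out degrees, ranked by total degree.

    In-degree counts edges arriving at the node as a target, out-degree edges
    leaving it as a regulator. The table is sorted by total degree descending
    (ties by node ID) and carries a 1-based ``rank`` column.
    """
    edges = _final_edges(net)
    nodes = sorted(set(edges["regulator"]) | set(edges["target"]))
    out_deg = edges["regulator"].value_counts()
    in_deg = edges["target"].value_counts()
    table = pd.DataFrame(
        {
            "gene": nodes,
            "in_degree": [int(in_deg.get(n, 0)) for n in nodes],
            "out_degree": [int(out_deg.get(n, 0)) for n in nodes],
        }
    )
    table["total_degree"] = table["in_degree"] + table["out_degree"]
    table = table.sort_values(
        ["total_degree", "gene"], ascending=[False, True]
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def to_graph(net: TestedNetwork, weighted: bool = True) -> nx.Graph:
    """Undirected projection of the final network.

    Nodes are inserted in sorted order and antiparallel edge weights are
    summed, so the graph (and everything seeded computed on it) is invariant
    to the input edge order.
    """
    edges = _final_edges(net)
    g = nx.Graph()
    g.add_nodes_from(sorted(set(edges["regulator"]) | set(edges["target"])))
    rows = sorted(
        zip(edges["regulator"], edges["target"], edges["importance"].astype(float))
    )
    for reg, tgt, w in rows:
        weight = w if weighted else 1.0
        if g.has_edge(reg, tgt):
            g[reg][tgt]["weight"] += weight
        else:
            g.add_edge(reg, tgt, weight=weight)
    return g


def detect_communities(
    net: TestedNetwork, seed: int = 42, weighted: bool = True, resolution: float = 1.0
) -> CommunityPartition:
    """Louvain gene modules on the undirected projection of the network.

    Edge weight is the importance (or 1 with ``weighted=False``); the run is
    deterministic given ``seed`` and independent of edge input order.
    Community labels are integers assigned by sorted smallest member.
    """
    g = to_graph(net, weighted=weighted)
    communities = nx.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=seed
    )
    modularity = nx.community.modularity(
        g, communities, weight="weight", resolution=resolution
    )
    ordered = sorted(communities, key=min)
    labels = {gene: i for i, comm in enumerate(ordered) for gene in comm}
    return CommunityPartition(labels=labels, modularity=float(modularity))


def module_profiles(
    net: TestedNetwork, partition: CommunityPartition, expr: CountMatrix
) -> pd.DataFrame:
    """Average mean-scaled expression profile of each community.

    Every member gene's profile is first divided by its own mean across
    samples (so each gene averages to 1), then profiles are averaged within
    each community. Returns a community x sample table.
    """
    missing = [g for g in partition.labels if g not in expr.values.index]
    if missing:
        raise KeyError(f"genes absent from the expression matrix: {sorted(missing)}")
    rows = {}
    for label in sorted(set(partition.labels.values())):
        members = partition.members(label)
        profiles = expr.values.loc[members]
        means = profiles.mean(axis=1)
        if (means == 0).any():
            zero = means.index[means == 0][0]
            raise ValueError(f"gene {zero!r} has zero mean expression")
        scaled = profiles.div(means, axis=0)
        rows[label] = scaled.mean(axis=0)
    out = pd.DataFrame(rows).T
    out.index.name = "community"
    return out
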