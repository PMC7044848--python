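"""Per-node measures of the transfer network.

Conventions, chosen once and used throughout:

* degree ``k`` counts *distinct neighbours* in the undirected view, so a
  reciprocated transfer pair contributes one to ``k``;
* strength ``s`` is the sum of incident edge weights (weighted degree),
  split into ``s_in``/``s_out`` on the directed graph;
* net connectivity ``delta = k_in - k_out`` is positive for "receiver"
  wards (fed by many places, discharging to few) and negative for
  "distributor" wards;
* clustering and the weighted nearest-neighbour degree are computed on
  the undirected projection (antiparallel weights summed), the convention
  of the literature those measures come from;
* betweenness is computed on the directed *unweighted* graph — transfer
  counts measure traffic, not distance — with fractional credit for
  shortest-path multiplicities, raw (unnormalised) by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx


def undirected_projection(net: nx.DiGraph, weighted: bool = True) -> nx.Graph:
    """Undirected view; weights of antiparallel edges are summed."""
    g = nx.Graph()
    g.add_nodes_from(net.nodes(data=True))
    for u, v, d in net.edges(data=True):
        w = d.get("weight", 1)
        if g.has_edge(u, v):
            g[u][v]["weight"] += w
        else:
            g.add_edge(u, v, weight=w)
    if not weighted:
        for _, _, d in g.edges(data=True):
            d["weight"] = 1
    return g


def degrees(net: nx.DiGraph) -> pd.DataFrame:
    """Degree variants, strengths and net connectivity, one row per node."""
    und = undirected_projection(net)
    nodes = sorted(net.nodes)
    k = dict(und.degree())
    k_in = dict(net.in_degree())
    k_out = dict(net.out_degree())
    s_in = dict(net.in_degree(weight="weight"))
    s_out = dict(net.out_degree(weight="weight"))
    df = pd.DataFrame(
        {
            "k": [k[u] for u in nodes],
            "k_in": [k_in[u] for u in nodes],
            "k_out": [k_out[u] for u in nodes],
            "s_in": [s_in[u] for u in nodes],
            "s_out": [s_out[u] for u in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )
    df["s"] = df["s_in"] + df["s_out"]
    df["delta"] = df["k_in"] - df["k_out"]
    return df


def local_clustering(net: nx.DiGraph) -> pd.Series:
    """Unweighted local clustering on the undirected simple projection."""
    und = undirected_projection(net, weighted=False)
    c = nx.clustering(und)
    nodes = sorted(net.nodes)
    return pd.Series([c[u] for u in nodes], index=pd.Index(nodes, name="node"), name="c_local")


def global_transitivity(net: nx.DiGraph) -> float:
    """Global clustering C = 3 * triangles / connected triples."""
    return float(nx.transitivity(undirected_projection(net, weighted=False)))


def betweenness(net: nx.DiGraph, normalized: bool = False) -> pd.Series:
    """Directed unweighted betweenness; raw path counts by default."""
    b = nx.betweenness_centrality(net, normalized=normalized, weight=None)
    nodes = sorted(net.nodes)
    return pd.Series([b[u] for u in nodes], index=pd.Index(nodes, name="node"), name="b")


def weighted_knn(net: nx.DiGraph) -> pd.Series:
    """Weighted average nearest-neighbour degree.

    knn_w(i) = (1/s_i) * sum_j w_ij * k_j over undirected neighbours j,
    where k_j is the neighbour's (unweighted, distinct-neighbour) degree.
    Isolated nodes are undefined (NaN).
    """
    und = undirected_projection(net)
    knn = nx.average_neighbor_degree(und, weight="weight")
    deg = dict(und.degree())
    nodes = sorted(net.nodes)
    vals = [knn[u] if deg[u] > 0 else np.nan for u in nodes]
    return pd.Series(vals, index=pd.Index(nodes, name="node"), name="knn_w")


def knn_curve(metrics: pd.DataFrame) -> pd.Series:
    """Mean knn_w among nodes of each degree k; isolated nodes excluded."""
    ok = metrics.dropna(subset=["knn_w"])
    ok = ok[ok["k"] > 0]
    return ok.groupby("k")["knn_w"].mean()


def compute_node_metrics(net: nx.DiGraph, normalized_betweenness: bool = False) -> pd.DataFrame:
    """The full per-node table: k, k_in, k_out, s_in, s_out, s, delta,
    c_local, b, knn_w."""
    df = degrees(net)
    df["c_local"] = local_clustering(net)
    df["b"] = betweenness(net, normalized=normalized_betweenness)
    df["knn_w"] = weighted_knn(net)
    return df
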