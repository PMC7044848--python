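"""Whole-network measures of the transfer network.

Measures that are undefined on degenerate inputs (an edgeless graph, a
regular graph for assortativity, a too-small component for path length)
return ``None`` rather than a misleading zero.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import networkx as nx

from .errors import InvalidParameterError
from .node_metrics import global_transitivity, undirected_projection


@dataclass
class GlobalMetrics:
    r: float | None  # reciprocity
    a: float | None  # degree assortativity (undirected projection)
    h: float | None  # flow hierarchy
    L: float | None  # average shortest path length
    C: float  # global transitivity
    n_nodes: int
    n_edges: int
    total_weight: int
    degree_histogram: dict[int, int]
    path_length_mode: str = "undirected_lcc"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["degree_histogram"] = {str(k): v for k, v in self.degree_histogram.items()}
        return d


def reciprocity(net: nx.DiGraph) -> float | None:
    """Fraction of directed edges whose antiparallel counterpart exists.

    Unweighted by construction: a transfer direction either exists or it
    does not, regardless of how often it was used.
    """
    if net.number_of_edges() == 0:
        return None
    return float(nx.overall_reciprocity(net))


def assortativity(net: nx.DiGraph) -> float | None:
    """Pearson correlation of degrees at the two ends of each edge.

    Computed on the undirected unweighted projection, counting both
    orientations of each edge.  Undefined (None) when end degrees have
    zero variance, e.g. on a cycle.
    """
    und = undirected_projection(net, weighted=False)
    if und.number_of_edges() < 2:
        return None
    deg = dict(und.degree())
    x, y = [], []
    for u, v in und.edges:
        x.extend((deg[u], deg[v]))
        y.extend((deg[v], deg[u]))
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    with np.errstate(invalid="ignore"):
        r = float(np.corrcoef(x, y)[0, 1])
    return None if np.isnan(r) else r


def flow_hierarchy(net: nx.DiGraph) -> float | None:
    """Fraction of directed edges not contained in any directed cycle.

    An edge lies on a cycle iff both endpoints belong to one strongly
    connected component; h = 1 exactly for acyclic flow.
    """
    if net.number_of_edges() == 0:
        return None
    return float(nx.flow_hierarchy(net))


def average_path_length(net: nx.DiGraph, mode: str = "undirected_lcc") -> float | None:
    """Mean unweighted shortest-path distance over reachable ordered pairs.

    ``undirected_lcc`` (default, the small-world reference convention)
    restricts to the largest connected component of the undirected
    projection; ``directed_lscc`` to the largest strongly connected
    component of the directed graph.
    """
    if mode == "undirected_lcc":
        und = undirected_projection(net, weighted=False)
        if und.number_of_nodes() == 0:
            return None
        comp = max(nx.connected_components(und), key=len)
        sub = und.subgraph(comp)
    elif mode == "directed_lscc":
        if net.number_of_nodes() == 0:
            return None
        comp = max(nx.strongly_connected_components(net), key=len)
        sub = net.subgraph(comp)
    else:
        raise InvalidParameterError(f"unknown path-length mode {mode!r}")
    if sub.number_of_nodes() < 2:
        return None
    return float(nx.average_shortest_path_length(sub))


def degree_histogram(net: nx.DiGraph) -> dict[int, int]:
    """Counts of nodes by distinct-neighbour degree k (undirected view)."""
    und = undirected_projection(net, weighted=False)
    hist: dict[int, int] = {}
    for _, d in und.degree():
        hist[d] = hist.get(d, 0) + 1
    return dict(sorted(hist.items()))


def compute_global_metrics(
    net: nx.DiGraph, path_length_mode: str = "undirected_lcc"
) -> GlobalMetrics:
    return GlobalMetrics(
        r=reciprocity(net),
        a=assortativity(net),
        h=flow_hierarchy(net),
        L=average_path_length(net, mode=path_length_mode),
        C=global_transitivity(net),
        n_nodes=net.number_of_nodes(),
        n_edges=net.number_of_edges(),
        total_weight=int(sum(d.get("weight", 1) for _, _, d in net.edges(data=True))),
        degree_histogram=degree_histogram(net),
        path_length_mode=path_length_mode,
    )
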