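"""Build weighted directed transfer networks from journeys; read/write them.

The transfer network is held as a :class:`networkx.DiGraph` whose integer
``weight`` edge attribute counts how many times the transfer occurred.
No self-edges exist (journeys are compacted first), and no per-admission
de-duplication is applied: a patient shuttling ward <-> CT three times
contributes six transfers, because each transfer is a use of resources.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path
from typing import IO, Iterable, Mapping

import networkx as nx

from .errors import FormatError, InvalidParameterError
from .ingest import PatientJourney

#: virtual endpoint nodes, optionally attached to every journey
ADMISSION_NODE = "ADMISSION"
DISCHARGE_NODE = "DISCHARGE"


def build_network(
    journeys: Iterable[PatientJourney],
    include_endpoints: bool = False,
    categories: Mapping[str, str] | None = None,
) -> nx.DiGraph:
    """Aggregate journeys into a weighted directed transfer network.

    Each consecutive pair (u, v) in each journey increments w(u, v) by
    one.  With ``include_endpoints``, virtual ADMISSION and DISCHARGE
    nodes are prepended and appended to every journey, which makes
    weighted in-flow equal out-flow at every real node (every patient who
    enters a ward later leaves it).

    A journey of length one contributes its node but no edge; an empty
    journey collection yields an empty network.
    """
    net = nx.DiGraph()
    for j in journeys:
        path = list(j.path)
        if not path:
            continue
        if include_endpoints:
            path = [ADMISSION_NODE, *path, DISCHARGE_NODE]
        net.add_nodes_from(path)
        for u, v in zip(path, path[1:]):
            if u == v:
                continue  # compaction upstream should prevent this
            if net.has_edge(u, v):
                net[u][v]["weight"] += 1
            else:
                net.add_edge(u, v, weight=1)
    if categories:
        for u in net.nodes:
            if u in categories:
                net.nodes[u]["category"] = categories[u]
    return net


def total_weight(net: nx.DiGraph) -> int:
    return int(sum(d["weight"] for _, _, d in net.edges(data=True)))


def write_network(
    net: nx.DiGraph, fmt: str, sink: str | Path | IO[str]
) -> None:
    """Write a transfer network as GraphML or weighted edge-list CSV."""
    if fmt == "graphml":
        nx.write_graphml(net, sink)
    elif fmt == "edgelist_csv":
        if isinstance(sink, (str, Path)):
            with open(sink, "w", newline="", encoding="utf-8") as fh:
                write_network(net, fmt, fh)
            return
        writer = csv.writer(sink)
        writer.writerow(["source", "target", "weight"])
        for u, v, d in net.edges(data=True):
            writer.writerow([u, v, int(d["weight"])])
    else:
        raise InvalidParameterError(f"unknown network format {fmt!r}")


def read_network(source: str | Path | IO[str], fmt: str) -> nx.DiGraph:
    """Read a transfer network written by :func:`write_network`.

    Weights must be positive integers; duplicate edge rows in an
    edge-list are summed with a warning.
    """
    if fmt == "graphml":
        g = nx.read_graphml(source)
        net = nx.DiGraph()
        net.add_nodes_from(g.nodes(data=True))
        for u, v, d in g.edges(data=True):
            w = _check_weight(d.get("weight"), f"{u}->{v}")
            if net.has_edge(u, v):
                warnings.warn(f"duplicate edge {u}->{v}; weights summed", stacklevel=2)
                net[u][v]["weight"] += w
            else:
                net.add_edge(u, v, weight=w)
        return net
    if fmt == "edgelist_csv":
        if isinstance(source, (str, Path)):
            with open(source, newline="", encoding="utf-8") as fh:
                return read_network(fh, fmt)
        reader = csv.DictReader(source)
        if reader.fieldnames is None or not {"source", "target", "weight"} <= set(
            reader.fieldnames
        ):
            raise FormatError("edge list must have columns: source, target, weight")
        net = nx.DiGraph()
        for row in reader:
            u, v = row["source"], row["target"]
            w = _check_weight(row["weight"], f"{u}->{v}")
            net.add_nodes_from([u, v])
            if net.has_edge(u, v):
                warnings.warn(f"duplicate edge {u}->{v}; weights summed", stacklevel=2)
                net[u][v]["weight"] += w
            else:
                net.add_edge(u, v, weight=w)
        return net
    raise InvalidParameterError(f"unknown network format {fmt!r}")


def _check_weight(value, edge: str) -> int:
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise FormatError(f"non-numeric weight on edge {edge}") from None
    if f != int(f):
        raise FormatError(f"non-integer weight {value!r} on edge {edge}")
    w = int(f)
    if w < 1:
        raise FormatError(f"non-positive weight {w} on edge {edge}")
    return w


def networks_equal(a: nx.DiGraph, b: nx.DiGraph) -> bool:
    """Exact structural equality: same nodes, edges and integer weights."""
    if set(a.nodes) != set(b.nodes) or set(a.edges) != set(b.edges):
        return False
    return all(int(a[u][v]["weight"]) == int(b[u][v]["weight"]) for u, v in a.edges)
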