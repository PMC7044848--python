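"""Independent brute-force implementations of every network measure.

These deliberately avoid the library code paths (and networkx's
algorithms): betweenness is counted by enumerating shortest paths over a
hand-rolled BFS, clustering by matrix triangle counts, assortativity by
a direct Pearson correlation over edge ends, flow hierarchy by an
explicit reachability closure, and path lengths by BFS.  They are only
ever run on tiny graphs.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np
import networkx as nx


def und_adjacency(net: nx.DiGraph):
    """Undirected 0/1 adjacency matrix and the sorted node list."""
    nodes = sorted(net.nodes)
    index = {u: i for i, u in enumerate(nodes)}
    a = np.zeros((len(nodes), len(nodes)), dtype=int)
    for u, v in net.edges:
        if u != v:
            a[index[u], index[v]] = 1
            a[index[v], index[u]] = 1
    return a, nodes


def bf_degrees(net: nx.DiGraph) -> dict:
    nodes = sorted(net.nodes)
    out = {}
    for u in nodes:
        in_nbrs = {x for x, y in net.edges if y == u}
        out_nbrs = {y for x, y in net.edges if x == u}
        s_in = sum(d["weight"] for x, y, d in net.edges(data=True) if y == u)
        s_out = sum(d["weight"] for x, y, d in net.edges(data=True) if x == u)
        out[u] = {
            "k": len(in_nbrs | out_nbrs),
            "k_in": len(in_nbrs),
            "k_out": len(out_nbrs),
            "s_in": s_in,
            "s_out": s_out,
            "s": s_in + s_out,
            "delta": len(in_nbrs) - len(out_nbrs),
        }
    return out


def bf_local_clustering(net: nx.DiGraph) -> dict:
    a, nodes = und_adjacency(net)
    a3 = a @ a @ a
    k = a.sum(axis=1)
    out = {}
    for i, u in enumerate(nodes):
        pairs = k[i] * (k[i] - 1) / 2
        out[u] = (a3[i, i] / 2) / pairs if pairs > 0 else 0.0
    return out


def bf_transitivity(net: nx.DiGraph) -> float:
    a, _ = und_adjacency(net)
    triangles = np.trace(a @ a @ a) / 6
    k = a.sum(axis=1)
    triples = (k * (k - 1) / 2).sum()
    return 3 * triangles / triples if triples > 0 else 0.0


def _bfs_dists(adj: dict, src):
    dist = {src: 0}
    q = deque([src])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def bf_betweenness(net: nx.DiGraph) -> dict:
    """Raw directed betweenness by exhaustive shortest-path enumeration.

    For every ordered pair (s, t), enumerates ALL shortest directed
    paths with a depth-limited DFS and credits each interior node the
    fraction of those paths it lies on.
    """
    nodes = sorted(net.nodes)
    adj = {u: sorted(net.successors(u)) for u in nodes}
    b = {u: 0.0 for u in nodes}
    for s in nodes:
        dist = _bfs_dists(adj, s)
        for t in dist:
            if t == s:
                continue
            limit = dist[t]
            paths: list[tuple] = []

            def dfs(u, path):
                if len(path) - 1 > limit:
                    return
                if u == t:
                    if len(path) - 1 == limit:
                        paths.append(tuple(path))
                    return
                for v in adj[u]:
                    if v not in path:
                        dfs(v, path + [v])

            dfs(s, [s])
            for path in paths:
                for v in path[1:-1]:
                    b[v] += 1.0 / len(paths)
    return b


def bf_knn_w(net: nx.DiGraph) -> dict:
    """Weighted nearest-neighbour degree on the undirected projection."""
    nodes = sorted(net.nodes)
    w = {}
    for u, v, d in net.edges(data=True):
        if u == v:
            continue
        key = (u, v) if u < v else (v, u)
        w[key] = w.get(key, 0) + d["weight"]
    nbrs = {u: set() for u in nodes}
    for (u, v) in w:
        nbrs[u].add(v)
        nbrs[v].add(u)
    k = {u: len(nbrs[u]) for u in nodes}
    out = {}
    for u in nodes:
        s = sum(w[(min(u, v), max(u, v))] for v in nbrs[u])
        if s == 0:
            out[u] = None
        else:
            out[u] = sum(w[(min(u, v), max(u, v))] * k[v] for v in nbrs[u]) / s
    return out


def bf_reciprocity(net: nx.DiGraph):
    edges = set(net.edges)
    if not edges:
        return None
    return sum(1 for (u, v) in edges if (v, u) in edges) / len(edges)


def bf_assortativity(net: nx.DiGraph):
    und = set()
    for u, v in net.edges:
        if u != v:
            und.add((min(u, v), max(u, v)))
    if len(und) < 2:
        return None
    deg = {u: 0 for u in net.nodes}
    for u, v in und:
        deg[u] += 1
        deg[v] += 1
    x, y = [], []
    for u, v in und:
        x += [deg[u], deg[v]]
        y += [deg[v], deg[u]]
    x, y = np.array(x, float), np.array(y, float)
    if x.std() == 0 or y.std() == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def bf_flow_hierarchy(net: nx.DiGraph):
    """1 - fraction of edges on directed cycles, via reachability closure."""
    edges = list(net.edges)
    if not edges:
        return None
    nodes = sorted(net.nodes)
    idx = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    reach = np.zeros((n, n), dtype=bool)
    for u, v in edges:
        reach[idx[u], idx[v]] = True
    for k in range(n):
        for i in range(n):
            if reach[i, k]:
                reach[i] |= reach[k]
    cyclic = sum(1 for u, v in edges if reach[idx[v], idx[u]])
    return 1 - cyclic / len(edges)


def bf_average_path_length(net: nx.DiGraph, mode: str = "undirected_lcc"):
    nodes = sorted(net.nodes)
    if mode == "undirected_lcc":
        adj = {u: set() for u in nodes}
        for u, v in net.edges:
            if u != v:
                adj[u].add(v)
                adj[v].add(u)
    else:
        adj = {u: set(net.successors(u)) for u in nodes}
    # components (weak/undirected vs strong by mutual reachability)
    if mode == "undirected_lcc":
        comps, seen = [], set()
        for u in nodes:
            if u in seen:
                continue
            comp = set(_bfs_dists(adj, u))
            comps.append(comp)
            seen |= comp
    else:
        comps = []
        remaining = set(nodes)
        while remaining:
            u = min(remaining)
            fwd = set(_bfs_dists(adj, u))
            radj = {x: {y for y in nodes if x in adj[y]} for x in nodes}
            bwd = set(_bfs_dists(radj, u))
            comp = fwd & bwd
            comps.append(comp)
            remaining -= comp
    comp = max(comps, key=len)
    if len(comp) < 2:
        return None
    total, pairs = 0, 0
    for s in comp:
        d = _bfs_dists({u: adj[u] & comp for u in comp}, s)
        for t in comp:
            if t != s:
                total += d[t]
                pairs += 1
    return total / pairs


def random_digraph(rng: np.random.Generator, n: int, p: float = 0.3, max_w: int = 5) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(f"n{i}" for i in range(n))
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < p:
                g.add_edge(f"n{i}", f"n{j}", weight=int(rng.integers(1, max_w + 1)))
    return g


def all_digraphs(n: int):
    """Every labelled simple digraph on n nodes, unit weights."""
    pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    for bits in itertools.product([0, 1], repeat=len(pairs)):
        g = nx.DiGraph()
        g.add_nodes_from(f"n{i}" for i in range(n))
        for (i, j), bit in zip(pairs, bits):
            if bit:
                g.add_edge(f"n{i}", f"n{j}", weight=1)
        yield g
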