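"""Small-world coefficients sigma and omega with null-model references.

Both coefficients compare the observed clustering C and characteristic
path length L (computed on the undirected, unweighted projection of the
largest connected component) against degree-preserving references:

    sigma = (C / C_random) / (L / L_random)
    omega = L_random / L  -  C / C_lattice

Random references come from degree-preserving double-edge swaps that
reject disconnecting moves.  Lattice references come from a greedy
latticization: nodes are placed on a ring in sorted-label order and
double-edge swaps are accepted only when they strictly reduce the total
circular edge length, pulling edges into a band around the ring — a
deterministic, annealing-free procedure that terminates when a full
sweep accepts no swap.  Every reference has exactly the original degree
sequence.

``omega`` is near 0 for small-world graphs, near -1 for lattices and
near +1 for random graphs; ``sigma`` well above 1 indicates
small-worldness (clustering far above random at near-random path
length).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np

from .errors import DegenerateReferenceError
from .node_metrics import undirected_projection


@dataclass
class SmallWorldResult:
    C: float
    L: float
    C_random: float
    L_random: float
    C_lattice: float
    sigma: float
    omega: float
    n_random: int
    n_lattice: int
    rewiring_per_edge: int
    seed: int

    def to_dict(self) -> dict:
        return asdict(self)


def _undirected_lcc(net: nx.DiGraph | nx.Graph) -> nx.Graph:
    und = undirected_projection(net, weighted=False) if net.is_directed() else nx.Graph(net)
    if und.number_of_edges() == 0:
        raise DegenerateReferenceError("network has no edges")
    comp = max(nx.connected_components(und), key=len)
    g = nx.Graph(und.subgraph(comp))
    if g.number_of_nodes() < 4:
        raise DegenerateReferenceError("largest component has fewer than 4 nodes")
    return g


def _is_complete(g: nx.Graph) -> bool:
    n = g.number_of_nodes()
    return g.number_of_edges() == n * (n - 1) // 2


def _seeds(seed: int, n: int, salt: int) -> list[int]:
    ss = np.random.SeedSequence(seed, spawn_key=(salt,))
    return [int(s) for s in ss.generate_state(n)]


def _randomized(g: nx.Graph, rewiring_per_edge: int, seed: int) -> nx.Graph:
    """One degree-preserving, connectivity-preserving rewired copy."""
    if _is_complete(g):
        return g.copy()  # no double swap can alter a complete graph
    h = g.copy()
    nswap = rewiring_per_edge * h.number_of_edges()
    try:
        nx.connected_double_edge_swap(h, nswap=nswap, seed=seed)
    except nx.NetworkXError as exc:
        raise DegenerateReferenceError(f"cannot rewire graph: {exc}") from exc
    return h


def _natural_key(label):
    """Ring-order sort key: numeric labels sort numerically, so graphs
    whose labels encode a ring position latticize onto that ring."""
    s = str(label)
    return (0, int(s), "") if s.isdigit() else (1, 0, s)


def _latticized(
    g: nx.Graph, seed: int, max_sweeps: int = 100, partner_tries: int = 40
) -> nx.Graph:
    """One greedy ring-band latticization of ``g``.

    Edges are visited longest-first; for each, up to ``partner_tries``
    random partner edges are examined and the swap pairing that most
    reduces total circular edge length is applied if it strictly
    improves.  Terminates when a sweep accepts nothing.
    """
    rng = random.Random(seed)
    nodes = sorted(g.nodes(), key=_natural_key)
    idx = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)

    def dist(i: int, j: int) -> int:
        d = abs(i - j)
        return d if d <= n - d else n - d

    adj = {u: set(g[u]) for u in g}
    edges = [tuple(e) for e in g.edges()]
    n_edges = len(edges)
    for _ in range(max_sweeps):
        accepted = 0
        order = sorted(
            range(n_edges), key=lambda i: -dist(idx[edges[i][0]], idx[edges[i][1]])
        )
        for e1 in order:
            a, b = edges[e1]
            ia, ib = idx[a], idx[b]
            d1 = dist(ia, ib)
            if d1 <= 1:
                continue  # already in the innermost band
            for _try in range(partner_tries):
                e2 = rng.randrange(n_edges)
                c, d = edges[e2]
                if len({a, b, c, d}) < 4:
                    continue
                ic, id_ = idx[c], idx[d]
                cur = d1 + dist(ic, id_)
                best = None
                best_cost = cur
                if d not in adj[a] and b not in adj[c]:
                    cost = dist(ia, id_) + dist(ic, ib)
                    if cost < best_cost:
                        best_cost, best = cost, ((a, d), (c, b))
                if c not in adj[a] and d not in adj[b]:
                    cost = dist(ia, ic) + dist(ib, id_)
                    if cost < best_cost:
                        best_cost, best = cost, ((a, c), (b, d))
                if best is not None:
                    (p, q), (r, s) = best
                    adj[a].discard(b); adj[b].discard(a)
                    adj[c].discard(d); adj[d].discard(c)
                    adj[p].add(q); adj[q].add(p)
                    adj[r].add(s); adj[s].add(r)
                    edges[e1] = (p, q)
                    edges[e2] = (r, s)
                    accepted += 1
                    break
        if accepted == 0:
            break
    h = nx.Graph()
    h.add_nodes_from(nodes)
    h.add_edges_from(edges)
    return h


def random_reference(
    net: nx.DiGraph | nx.Graph,
    n_refs: int = 10,
    rewiring_per_edge: int = 10,
    seed: int = 0,
    return_graphs: bool = False,
):
    """Mean clustering and path length over rewired random references."""
    g = _undirected_lcc(net)
    refs = [
        _randomized(g, rewiring_per_edge, s)
        for s in _seeds(seed, n_refs, salt=0)
    ]
    c = float(np.mean([nx.transitivity(r) for r in refs]))
    length = float(np.mean([nx.average_shortest_path_length(r) for r in refs]))
    if return_graphs:
        return c, length, refs
    return c, length


def lattice_reference(
    net: nx.DiGraph | nx.Graph,
    n_refs: int = 10,
    seed: int = 0,
    return_graphs: bool = False,
):
    """Mean clustering over greedily latticized references."""
    g = _undirected_lcc(net)
    refs = [_latticized(g, s) for s in _seeds(seed, n_refs, salt=1)]
    c = float(np.mean([nx.transitivity(r) for r in refs]))
    if return_graphs:
        return c, refs
    return c


def small_world_coefficients(
    net: nx.DiGraph | nx.Graph,
    n_refs: int = 10,
    rewiring_per_edge: int = 10,
    seed: int = 0,
) -> SmallWorldResult:
    """Compute sigma and omega with all five ingredient statistics."""
    g = _undirected_lcc(net)
    c_obs = float(nx.transitivity(g))
    l_obs = float(nx.average_shortest_path_length(g))
    c_rand, l_rand = random_reference(g, n_refs, rewiring_per_edge, seed)
    c_latt = lattice_reference(g, n_refs, seed)
    if c_rand == 0 or l_obs == 0 or c_latt == 0:
        raise DegenerateReferenceError(
            "degenerate references (zero clustering or path length)"
        )
    sigma = (c_obs / c_rand) / (l_obs / l_rand)
    omega = l_rand / l_obs - c_obs / c_latt
    return SmallWorldResult(
        C=c_obs,
        L=l_obs,
        C_random=c_rand,
        L_random=l_rand,
        C_lattice=c_latt,
        sigma=float(sigma),
        omega=float(omega),
        n_random=n_refs,
        n_lattice=n_refs,
        rewiring_per_edge=rewiring_per_edge,
        seed=seed,
    )
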