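"""Synthetic hospital configurations and patient-movement logs.

Real inpatient location extracts are rarely shareable, so this module
generates movement-event logs with the structural features the analysis
assumes: every admission enters through an emergency node, moves between
wards according to a row-stochastic routing matrix that includes
investigation round-trips (ward -> radiology -> ward arises naturally from
routing mass into and out of investigation locations), and ends in an
absorbing DISCHARGE state.  It also provides canonical reference graphs
(stars, rings, Watts-Strogatz, ...) used to validate the network measures.

Lengths of stay are drawn from an exponential law per location.  The
downstream analysis uses only the *ordering* of events, so the duration
distribution is inert; exponential stays are chosen for simplicity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from .errors import InvalidParameterError, SimulationError, ValidationError
from .ingest import MovementEvent

DISCHARGE = "DISCHARGE"

#: hard cap on events per admission; hitting it indicates routing whose
#: absorption time is pathologically long and aborts the simulation.
MAX_EVENTS_PER_ADMISSION = 200

_CATEGORY_POOL = [
    "emergency",
    "investigations",
    "theatres",
    "critical_care",
    "surgical",
    "medical",
    "paediatrics",
    "rehabilitation",
    "clinics",
    "high_dependency",
]


@dataclass
class HospitalConfig:
    """A synthetic hospital: locations, categories, routing and stay times.

    Attributes
    ----------
    locations:
        Location identifiers (wards, investigation suites, the emergency
        entry point). ``DISCHARGE`` is *not* a location; it is the
        absorbing terminal state of the routing chain.
    categories:
        Mapping of location id to care-category label, used to build the
        agglomerated ("categorised") network.
    routing:
        ``routing[u][v]`` is the probability that a patient in ``u`` moves
        next to ``v``; targets include ``DISCHARGE``. Rows sum to one.
    entry_location:
        Where every admission starts (e.g. ``"AE"``).
    designated_hubs:
        Locations deliberately given disproportionate inbound routing
        mass, so hub recovery can be tested end to end.
    mean_stay:
        Mean length of stay per location, in hours.
    """

    locations: list[str]
    categories: dict[str, str]
    routing: dict[str, dict[str, float]]
    entry_location: str
    designated_hubs: list[str] = field(default_factory=list)
    mean_stay: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        """Check all structural invariants; raise ValidationError if broken."""
        locset = set(self.locations)
        if DISCHARGE in locset:
            raise ValidationError("DISCHARGE is a terminal state, not a location")
        if self.entry_location not in locset:
            raise ValidationError(
                f"entry location {self.entry_location!r} not among locations"
            )
        for hub in self.designated_hubs:
            if hub not in locset:
                raise ValidationError(f"designated hub {hub!r} not among locations")
        if DISCHARGE in self.routing:
            if any(p > 0 for p in self.routing[DISCHARGE].values()):
                raise ValidationError("DISCHARGE must be absorbing")
        for u in self.locations:
            row = self.routing.get(u)
            if row is None:
                raise ValidationError(f"location {u!r} has no routing row")
            total = math.fsum(row.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(
                    f"routing row for {u!r} sums to {total!r}, not 1"
                )
            if any(p < 0 for p in row.values()):
                raise ValidationError(f"negative routing probability from {u!r}")
            for v in row:
                if v != DISCHARGE and v not in locset:
                    raise ValidationError(f"routing target {v!r} unknown")
            if row.get(u, 0.0) > 0:
                raise ValidationError(f"self-transition at {u!r} not allowed")
        if not self._discharge_reachable():
            raise ValidationError(
                "DISCHARGE unreachable from entry location; chain would not terminate"
            )
        for u, stay in self.mean_stay.items():
            if stay <= 0:
                raise ValidationError(f"non-positive mean stay at {u!r}")

    def _discharge_reachable(self) -> bool:
        seen = {self.entry_location}
        frontier = [self.entry_location]
        while frontier:
            u = frontier.pop()
            for v, p in self.routing.get(u, {}).items():
                if p <= 0:
                    continue
                if v == DISCHARGE:
                    return True
                if v not in seen:
                    seen.add(v)
                    frontier.append(v)
        return False

    # -- JSON round trip ---------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "locations": self.locations,
                "categories": self.categories,
                "routing": self.routing,
                "entry_location": self.entry_location,
                "designated_hubs": self.designated_hubs,
                "mean_stay": self.mean_stay,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "HospitalConfig":
        raw = json.loads(text)
        cfg = cls(
            locations=list(raw["locations"]),
            categories=dict(raw["categories"]),
            routing={u: dict(row) for u, row in raw["routing"].items()},
            entry_location=raw["entry_location"],
            designated_hubs=list(raw.get("designated_hubs", [])),
            mean_stay=dict(raw.get("mean_stay", {})),
        )
        cfg.validate()
        return cfg


def generate_hospital_config(
    n_wards: int,
    n_categories: int,
    hub_fraction: float,
    seed: int,
) -> HospitalConfig:
    """Generate a random hospital whose routing plants recognisable hubs.

    ``ceil(hub_fraction * n_wards)`` wards receive inbound routing mass at
    least three times the median non-hub ward, so that degree- and
    betweenness-based hub classification has a known ground truth.
    Deterministic for a fixed seed.
    """
    if n_wards <= 0 or n_categories <= 0:
        raise InvalidParameterError("n_wards and n_categories must be positive")
    if n_categories > n_wards:
        raise InvalidParameterError("n_categories cannot exceed n_wards")
    if not 0 < hub_fraction < 1:
        raise InvalidParameterError("hub_fraction must lie strictly in (0, 1)")
    if n_wards < 3:
        raise InvalidParameterError("need at least 3 wards (entry, ward, hub)")

    rng = np.random.default_rng(seed)
    entry = "AE"
    locations = [entry] + [f"W{i:02d}" for i in range(1, n_wards)]
    n_hubs = math.ceil(hub_fraction * n_wards)
    non_entry = locations[1:]
    if n_hubs > len(non_entry):
        raise InvalidParameterError("hub_fraction leaves no non-hub wards")
    hubs = sorted(rng.choice(non_entry, size=n_hubs, replace=False).tolist())

    # category labels; the entry node is always "emergency"
    labels = list(_CATEGORY_POOL)
    while len(labels) < n_categories:
        labels.append(f"category_{len(labels) + 1}")
    labels = labels[:n_categories]
    categories = {entry: labels[0]}
    others = non_entry.copy()
    rng.shuffle(others)
    for i, loc in enumerate(others):
        if i < n_categories - 1:
            categories[loc] = labels[i + 1]  # guarantee every label occurs
        else:
            categories[loc] = labels[int(rng.integers(1, n_categories))] if n_categories > 1 else labels[0]

    hub_boost = 8.0
    attractiveness = {
        loc: (hub_boost * rng.uniform(0.8, 1.2) if loc in hubs else rng.uniform(0.3, 1.7))
        for loc in locations
    }

    # Real location graphs are structurally sparse — most ward pairs never
    # exchange patients — which is what gives the degree distribution its
    # spread.  Ordinary wards share a small symmetric neighbourhood
    # (transfer corridors are used in both directions), hubs exchange with
    # everyone (investigation/theatre round-trips), and the emergency
    # entry triages broadly but one-way: it is a pure distributor.
    max_out = max(2, min(n_wards - 2, 8))
    hub_set = set(hubs)
    plain = [v for v in locations if v != entry and v not in hub_set]
    nbr: dict[str, set[str]] = {u: set() for u in locations}
    for u in plain:
        pool = [v for v in plain if v != u]
        if pool:
            n_out = int(rng.integers(2, max_out + 1))
            for v in rng.choice(pool, size=min(n_out, len(pool)), replace=False):
                nbr[u].add(v)
                nbr[v].add(u)

    routing: dict[str, dict[str, float]] = {}
    for u in locations:
        p_discharge = 0.05 if u == entry else 0.30
        if u == entry or u in hub_set:
            targets = sorted(v for v in locations if v != u)
        else:
            targets = sorted(nbr[u] | (hub_set - {u}))
        w = np.array([attractiveness[v] for v in targets])
        w = w / w.sum() * (1.0 - p_discharge)
        row = {v: float(p) for v, p in zip(targets, w)}
        row[DISCHARGE] = p_discharge
        # exact renormalisation guards against float drift
        total = math.fsum(row.values())
        routing[u] = {v: p / total for v, p in row.items()}

    mean_stay = {
        loc: float(rng.uniform(2.0, 8.0) if loc == entry else rng.uniform(4.0, 72.0))
        for loc in locations
    }

    cfg = HospitalConfig(
        locations=locations,
        categories=categories,
        routing=routing,
        entry_location=entry,
        designated_hubs=hubs,
        mean_stay=mean_stay,
    )
    cfg.validate()
    _check_hub_mass(cfg)
    return cfg


def _check_hub_mass(cfg: HospitalConfig) -> None:
    """Assert the planted-hub guarantee: inbound mass >= 3x non-hub median."""
    inbound = {v: 0.0 for v in cfg.locations}
    for u in cfg.locations:
        for v, p in cfg.routing[u].items():
            if v != DISCHARGE:
                inbound[v] += p
    non_hub = [m for v, m in inbound.items()
               if v not in cfg.designated_hubs and v != cfg.entry_location]
    med = float(np.median(non_hub)) if non_hub else 0.0
    for hub in cfg.designated_hubs:
        if inbound[hub] < 3.0 * med:
            raise ValidationError(
                f"designated hub {hub!r} inbound mass {inbound[hub]:.3f} "
                f"< 3x median non-hub mass {med:.3f}"
            )


def simulate_admissions(
    config: HospitalConfig,
    n_admissions: int,
    start_time: datetime | None = None,
    seed: int = 0,
    missing_exit_rate: float = 0.0,
    duplicate_rate: float = 0.0,
) -> list[MovementEvent]:
    """Simulate patient journeys; return their movement events in order.

    Each admission starts at the entry location and walks the routing
    chain until DISCHARGE is drawn.  Events within an admission are
    contiguous, strictly increasing intervals; durations are exponential
    with the location's mean stay.  The random stream is split
    deterministically per admission, so increasing ``n_admissions`` does
    not reshuffle earlier journeys, and a fixed seed reproduces the log
    byte for byte.

    ``missing_exit_rate`` and ``duplicate_rate`` optionally inject the two
    defects that real extracts exhibit (rows missing exit timestamps and
    duplicated rows); they draw from a separate substream so the clean log
    is unchanged when both are zero.
    """
    if n_admissions < 0:
        raise InvalidParameterError("n_admissions must be non-negative")
    config.validate()
    if start_time is None:
        start_time = datetime(2024, 1, 1)

    events: list[MovementEvent] = []
    width = max(6, len(str(max(n_admissions, 1))))
    for i in range(n_admissions):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))
        noise_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i, 1)))
        admission_id = f"A{i:0{width}d}"
        t = start_time + timedelta(minutes=30 * i)
        loc = config.entry_location
        n_events = 0
        while True:
            if n_events >= MAX_EVENTS_PER_ADMISSION:
                raise SimulationError(
                    f"admission {admission_id} exceeded "
                    f"{MAX_EVENTS_PER_ADMISSION} events; routing is "
                    "effectively non-absorbing"
                )
            stay_h = max(float(rng.exponential(config.mean_stay.get(loc, 12.0))), 1e-3)
            exit_t = t + timedelta(hours=stay_h)
            ev = MovementEvent(admission_id, loc, t, exit_t)
            if missing_exit_rate > 0 and noise_rng.random() < missing_exit_rate:
                ev = MovementEvent(admission_id, loc, t, None)
            events.append(ev)
            if duplicate_rate > 0 and noise_rng.random() < duplicate_rate:
                events.append(ev)
            n_events += 1
            row = config.routing[loc]
            targets = sorted(row)  # deterministic order
            probs = np.array([row[v] for v in targets])
            nxt = targets[int(rng.choice(len(targets), p=probs / probs.sum()))]
            if nxt == DISCHARGE:
                break
            loc, t = nxt, exit_t
    return events


_UNDIRECTED_KINDS = {
    "erdos_renyi",
    "watts_strogatz",
    "barabasi_albert",
    "ring_lattice",
    "star",
    "path",
    "cycle",
}


def generate_reference_graph(
    kind: str,
    params: Mapping[str, float],
    seed: int = 0,
) -> nx.DiGraph:
    """Return a canonical test graph as a unit-weight transfer network.

    Undirected families are emitted as symmetric directed edge pairs so
    that the directed measures see them as reciprocal traffic.
    """
    p = dict(params)
    if kind == "erdos_renyi":
        g = nx.gnp_random_graph(int(p["n"]), float(p["p"]), seed=seed)
    elif kind == "watts_strogatz":
        g = nx.watts_strogatz_graph(int(p["n"]), int(p["k"]), float(p["p"]), seed=seed)
    elif kind == "barabasi_albert":
        g = nx.barabasi_albert_graph(int(p["n"]), int(p["m"]), seed=seed)
    elif kind == "ring_lattice":
        g = nx.watts_strogatz_graph(int(p["n"]), int(p["k"]), 0.0)
    elif kind == "star":
        g = nx.star_graph(int(p["n"]) - 1)
    elif kind == "path":
        g = nx.path_graph(int(p["n"]))
    elif kind == "cycle":
        g = nx.cycle_graph(int(p["n"]))
    else:
        raise InvalidParameterError(f"unknown reference graph kind {kind!r}")

    net = nx.DiGraph()
    net.add_nodes_from(str(u) for u in g.nodes())
    for u, v in g.edges():
        net.add_edge(str(u), str(v), weight=1)
        net.add_edge(str(v), str(u), weight=1)
    return net


def count_transfers(events: Iterable[MovementEvent]) -> int:
    """Number of transfers implied by an event log: events minus admissions.

    Holds exactly for clean simulator output, where every admission's
    events are contiguous and each event after the first is one transfer.
    """
    n_events = 0
    admissions = set()
    for ev in events:
        n_events += 1
        admissions.add(ev.admission_id)
    return n_events - len(admissions)
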