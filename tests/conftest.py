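from __future__ import annotations

import io
from datetime import datetime

import networkx as nx
import numpy as np
import pytest

from careflow.ingest import MovementEvent, PatientJourney
from careflow.simulate import generate_hospital_config, simulate_admissions


def dinet(edges) -> nx.DiGraph:
    """Directed weighted network from (u, v, w) triples."""
    g = nx.DiGraph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    return g


@pytest.fixture
def triangle_sym() -> nx.DiGraph:
    """Undirected triangle encoded as symmetric directed pairs."""
    return dinet(
        [(u, v, 1) for u, v in
         [("A", "B"), ("B", "A"), ("B", "C"), ("C", "B"), ("A", "C"), ("C", "A")]]
    )


@pytest.fixture
def small_hospital():
    """A 12-ward synthetic hospital with 300 admissions (deterministic)."""
    cfg = generate_hospital_config(n_wards=12, n_categories=4, hub_fraction=0.2, seed=11)
    events = simulate_admissions(cfg, 300, start_time=datetime(2024, 1, 1), seed=11)
    return cfg, events


@pytest.fixture
def events_csv(small_hospital) -> io.StringIO:
    from careflow.ingest import write_movement_records

    _, events = small_hospital
    buf = io.StringIO()
    write_movement_records(events, buf)
    buf.seek(0)
    return buf


def make_journeys(paths) -> list[PatientJourney]:
    return [PatientJourney(f"A{i}", tuple(p)) for i, p in enumerate(paths)]


def make_events(rows) -> list[MovementEvent]:
    """rows: (admission, location, entry_hour, exit_hour_or_None)."""
    base = datetime(2024, 1, 1)
    out = []
    for adm, loc, h_in, h_out in rows:
        from datetime import timedelta

        out.append(
            MovementEvent(
                adm,
                loc,
                base + timedelta(hours=h_in),
                None if h_out is None else base + timedelta(hours=h_out),
            )
        )
    return out


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
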