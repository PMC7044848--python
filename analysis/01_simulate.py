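#!/usr/bin/env python
"""Simulate the study cohort: a synthetic hospital and its movement log.

Generates a 40-location hospital (emergency entry, designated
high-traffic hubs, 8 care categories) and 4,000 unplanned admissions
walking its routing chain until discharge, then writes the movement
event log, the hospital configuration and the location -> category map
under results/data/.  Everything is deterministic for SEED.
"""

from pathlib import Path

from careflow.ingest import write_movement_records
from careflow.simulate import generate_hospital_config, simulate_admissions

SEED = 42
N_WARDS = 40
N_CATEGORIES = 8
HUB_FRACTION = 0.1
N_ADMISSIONS = 4000

OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = generate_hospital_config(N_WARDS, N_CATEGORIES, HUB_FRACTION, seed=SEED)
    events = simulate_admissions(cfg, N_ADMISSIONS, seed=SEED)

    write_movement_records(events, OUT / "events.csv")
    (OUT / "config.json").write_text(cfg.to_json())
    with open(OUT / "category_map.csv", "w") as fh:
        fh.write("location,category\n")
        for loc in cfg.locations:
            fh.write(f"{loc},{cfg.categories[loc]}\n")

    n_adm = len({e.admission_id for e in events})
    print(f"simulated {n_adm} admissions, {len(events)} movement events")
    print(f"designated hubs: {', '.join(cfg.designated_hubs)}")
    print(f"wrote events.csv, config.json, category_map.csv to {OUT}")


if __name__ == "__main__":
    main()
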