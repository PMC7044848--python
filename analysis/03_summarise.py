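#!/usr/bin/env python
"""Summarise the analysis report into the headline tables.

Reads results/report.json and writes results/summary.csv (one row per
network variant with the headline statistics) and
results/hubs_bottlenecks.csv (the four-way ward classification),
printing both.
"""

import json
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    report = json.loads((ROOT / "report.json").read_text())

    rows = []
    hub_rows = []
    for net in report["networks"]:
        name = net["name"]
        gm = net["global_metrics"]
        pl = net.get("powerlaw", {})
        sc = net.get("strength_scaling", {})
        sw = net.get("smallworld", {})
        rows.append(
            {
                "network": name,
                "n_nodes": gm["n_nodes"],
                "n_edges": gm["n_edges"],
                "total_weight": gm["total_weight"],
                "reciprocity": gm["r"],
                "assortativity": gm["a"],
                "flow_hierarchy": gm["h"],
                "transitivity": gm["C"],
                "avg_path_length": gm["L"],
                "gamma": pl.get("gamma"),
                "gamma_p": pl.get("p_value"),
                "beta": sc.get("beta"),
                "sigma": sw.get("sigma"),
                "omega": sw.get("omega"),
            }
        )
        if "skipped" not in net["classification"]:
            for r in net["classification"]["nodes"]:
                hub_rows.append({"network": name, **r})

    summary = pd.DataFrame(rows).set_index("network")
    summary.to_csv(ROOT / "summary.csv")
    print(summary.T.to_string())

    hubs = pd.DataFrame(hub_rows)
    hubs.to_csv(ROOT / "hubs_bottlenecks.csv", index=False)
    interesting = hubs[hubs.category != "neither"]
    print("\nhub/bottleneck wards:")
    print(interesting.to_string(index=False))


if __name__ == "__main__":
    main()
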