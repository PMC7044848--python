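"""End-to-end orchestration: events -> journeys -> networks -> report.

``run_pipeline`` ingests a movement log, builds the ward-level network
(and, when a category map is supplied, the categorised network), and
runs every analysis stage on each, collecting results into one
machine-readable report.  A failing stage is recorded as a skipped block
with its reason; the rest of the report is still produced.  Identical
inputs and seeds yield identical reports apart from the ``generated_at``
timestamp, which can be disabled for byte-for-byte comparison.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import IO, Callable

import networkx as nx
import pandas as pd

from . import __version__
from .build import build_network, total_weight
from .classify import classify_hubs_bottlenecks
from .errors import CareflowError
from .fits import (
    fit_betweenness_quadratic,
    fit_discrete_powerlaw,
    fit_strength_scaling,
)
from .global_metrics import compute_global_metrics
from .ingest import (
    PatientJourney,
    apply_category_map,
    assemble_journeys,
    read_movement_records,
)
from .node_metrics import compute_node_metrics
from .smallworld import small_world_coefficients

logger = logging.getLogger("careflow")


@dataclass
class PipelineOptions:
    """All knobs of the analysis, echoed into the report's provenance."""

    seed: int = 0
    quantile: float = 0.80
    b_gof: int = 1000
    b_ci: int = 1000
    n_refs: int = 10
    rewiring_per_edge: int = 10
    powerlaw_min_tail: int = 10
    flag_threshold: float = 2.0
    hub_metric: str = "k"
    normalized_betweenness: bool = False
    #: endpoints default: off for the ward-level network, on for the
    #: categorised one (the category-level convention shows admission and
    #: discharge explicitly); None means "use that default".
    include_endpoints: bool | None = None
    unmapped_policy: str = "error"
    include_timestamp: bool = True


def _safe(name: str, fn: Callable[[], dict | list]) -> dict | list:
    t0 = time.perf_counter()
    try:
        result = fn()
        logger.info("stage %-22s ok     (%.2fs)", name, time.perf_counter() - t0)
        return result
    except CareflowError as exc:
        logger.warning("stage %-22s skipped: %s", name, exc)
        return {"skipped": True, "reason": str(exc)}


def _json_safe(value):
    if isinstance(value, float) and math.isnan(value):
        return None
    return value


def analyse_network(
    net: nx.DiGraph,
    name: str,
    options: PipelineOptions,
    n_journeys: int | None = None,
    include_endpoints: bool = False,
) -> dict:
    """Run every analysis stage on one transfer network."""
    report: dict = {"name": name}
    report["summary"] = _safe(
        f"{name}.summary",
        lambda: {
            "n_nodes": net.number_of_nodes(),
            "n_edges": net.number_of_edges(),
            "total_weight": total_weight(net),
            "n_journeys": n_journeys,
            "include_endpoints": include_endpoints,
        },
    )

    metrics: pd.DataFrame | None = None

    def node_block() -> list:
        nonlocal metrics
        metrics = compute_node_metrics(
            net, normalized_betweenness=options.normalized_betweenness
        )
        return [
            {
                "node": str(node),
                **{
                    c: _json_safe(
                        float(row[c]) if c in ("c_local", "b", "knn_w") else int(row[c])
                    )
                    for c in metrics.columns
                },
            }
            for node, row in metrics.iterrows()
        ]

    report["node_metrics"] = _safe(f"{name}.node_metrics", node_block)
    report["global_metrics"] = _safe(
        f"{name}.global_metrics", lambda: compute_global_metrics(net).to_dict()
    )

    if metrics is not None:
        degree_samples = metrics.loc[metrics["k"] >= 1, "k"].to_numpy()
        report["powerlaw"] = _safe(
            f"{name}.powerlaw",
            lambda: fit_discrete_powerlaw(
                degree_samples,
                xmin="auto",
                b_gof=options.b_gof,
                b_ci=options.b_ci,
                seed=options.seed,
                min_tail=options.powerlaw_min_tail,
            ).to_dict(),
        )
        report["strength_scaling"] = _safe(
            f"{name}.strength_scaling",
            lambda: fit_strength_scaling(metrics).to_dict(),
        )
        report["betweenness_quadratic"] = _safe(
            f"{name}.betweenness_quadratic",
            lambda: fit_betweenness_quadratic(
                metrics, flag_threshold=options.flag_threshold
            ).to_dict(),
        )

        def classify_block() -> dict:
            hb = classify_hubs_bottlenecks(
                metrics, quantile=options.quantile, hub_metric=options.hub_metric
            )
            return {
                "quantile": hb.quantile,
                "hub_metric": hb.hub_metric,
                "hub_threshold_value": hb.hub_threshold_value,
                "bottleneck_threshold_value": hb.bottleneck_threshold_value,
                "nodes": hb.to_records(),
            }

        report["classification"] = _safe(f"{name}.classification", classify_block)
    else:  # pragma: no cover - only when node metrics failed
        for key in ("powerlaw", "strength_scaling", "betweenness_quadratic", "classification"):
            report[key] = {"skipped": True, "reason": "node metrics unavailable"}

    report["smallworld"] = _safe(
        f"{name}.smallworld",
        lambda: small_world_coefficients(
            net,
            n_refs=options.n_refs,
            rewiring_per_edge=options.rewiring_per_edge,
            seed=options.seed,
        ).to_dict(),
    )
    return report


def run_pipeline(
    events_source: str | Path | IO[str],
    category_map: dict[str, str] | None = None,
    options: PipelineOptions | None = None,
) -> dict:
    """Full analysis of a movement log; returns the report dict.

    Builds the ward-level network (virtual endpoints off by default) and,
    when ``category_map`` is given, the categorised network (endpoints on
    by default, so admission and discharge appear as explicit nodes).
    """
    options = options or PipelineOptions()
    parsed = read_movement_records(events_source)
    logger.info("ingest: %d events, %d rejects", len(parsed.events), len(parsed.rejects))
    assembled = assemble_journeys(parsed.events)
    journeys = assembled.journeys

    networks: list[dict] = []

    endpoints_ward = bool(options.include_endpoints) if options.include_endpoints is not None else False
    ward_net = build_network(journeys, include_endpoints=endpoints_ward)
    networks.append(
        analyse_network(
            ward_net,
            "ward",
            options,
            n_journeys=len(journeys),
            include_endpoints=endpoints_ward,
        )
    )

    if category_map is not None:
        endpoints_cat = (
            bool(options.include_endpoints) if options.include_endpoints is not None else True
        )
        cat_journeys = apply_category_map(
            journeys, category_map, unmapped_policy=options.unmapped_policy
        )
        cat_net = build_network(cat_journeys, include_endpoints=endpoints_cat)
        networks.append(
            analyse_network(
                cat_net,
                "category",
                options,
                n_journeys=len(cat_journeys),
                include_endpoints=endpoints_cat,
            )
        )

    provenance = {
        "tool": "careflow",
        "version": __version__,
        "seed": options.seed,
        "parameters": {
            k: v
            for k, v in asdict(options).items()
            if k not in ("seed", "include_timestamp")
        },
        "inputs": [str(events_source) if isinstance(events_source, (str, Path)) else "<stream>"]
        + (["<category map>"] if category_map is not None else []),
        "generated_at": (
            datetime.now(timezone.utc).isoformat() if options.include_timestamp else None
        ),
    }
    provenance["parameters"]["n_rejected_rows"] = len(parsed.rejects)
    provenance["parameters"]["n_ambiguous_admissions"] = len(assembled.ambiguous_admissions)
    return {"provenance": provenance, "networks": networks}


def strip_volatile(report: dict) -> dict:
    """Copy of a report with run-time-varying fields removed, for
    determinism comparisons."""
    import copy

    out = copy.deepcopy(report)
    out.get("provenance", {}).pop("generated_at", None)
    return out


def journeys_from_events_file(source: str | Path | IO[str]) -> list[PatientJourney]:
    """Convenience: parse a movement CSV straight to compacted journeys."""
    return assemble_journeys(read_movement_records(source).events).journeys
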