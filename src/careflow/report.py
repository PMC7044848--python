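"""Machine-readable analysis report: schema and validation.

The pipeline emits one JSON report per network variant.  The schema is
defined here as pydantic models; the JSON-schema document shipped with
the package (``data/report_schema.json``) is exported from these models,
and :func:`validate_report` checks a report against them.  Every
analytic block is either present or explicitly marked skipped with a
reason, so a partial run still yields a self-describing report.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Literal, Union

from pydantic import BaseModel, ConfigDict


class SkippedBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    skipped: Literal[True]
    reason: str


class NetworkSummary(BaseModel):
    n_nodes: int
    n_edges: int
    total_weight: int
    n_journeys: int | None = None
    include_endpoints: bool


class GlobalMetricsBlock(BaseModel):
    r: float | None
    a: float | None
    h: float | None
    L: float | None
    C: float
    n_nodes: int
    n_edges: int
    total_weight: int
    degree_histogram: dict[str, int]
    path_length_mode: str


class NodeMetricsRow(BaseModel):
    node: str
    k: int
    k_in: int
    k_out: int
    s_in: int
    s_out: int
    s: int
    delta: int
    c_local: float
    b: float
    knn_w: float | None


class PowerLawBlock(BaseModel):
    gamma: float
    xmin: int
    ks: float
    p_value: float | None
    ci_low: float | None
    ci_high: float | None
    n_tail: int
    b_gof: int
    b_ci: int
    seed: int


class ScalingBlock(BaseModel):
    beta: float
    intercept: float
    mean_weight: float
    r_squared: float


class FlaggedNode(BaseModel):
    node: str
    residual: float
    direction: Literal["high", "low"]


class QuadraticBlock(BaseModel):
    fit_coefficients: list[float]
    residual_sd: float
    flagged: list[FlaggedNode]


class SmallWorldBlock(BaseModel):
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


class ClassificationRow(BaseModel):
    node: str
    is_hub: bool
    is_bottleneck: bool
    category: Literal[
        "hub_bottleneck", "hub_non_bottleneck", "non_hub_bottleneck", "neither"
    ]


class ClassificationBlock(BaseModel):
    quantile: float
    hub_metric: str
    hub_threshold_value: float
    bottleneck_threshold_value: float
    nodes: list[ClassificationRow]


class Provenance(BaseModel):
    tool: str
    version: str
    seed: int
    parameters: dict[str, Union[int, float, str, bool, None]]
    inputs: list[str]
    generated_at: str | None = None


class NetworkReport(BaseModel):
    name: str
    summary: Union[NetworkSummary, SkippedBlock]
    global_metrics: Union[GlobalMetricsBlock, SkippedBlock]
    node_metrics: Union[list[NodeMetricsRow], SkippedBlock]
    powerlaw: Union[PowerLawBlock, SkippedBlock]
    strength_scaling: Union[ScalingBlock, SkippedBlock]
    betweenness_quadratic: Union[QuadraticBlock, SkippedBlock]
    smallworld: Union[SmallWorldBlock, SkippedBlock]
    classification: Union[ClassificationBlock, SkippedBlock]


class AnalysisReport(BaseModel):
    provenance: Provenance
    networks: list[NetworkReport]


def validate_report(report: dict) -> AnalysisReport:
    """Validate a report dict against the schema; raises on violation."""
    return AnalysisReport.model_validate(report)


def published_schema() -> dict:
    """The JSON schema document shipped with the package."""
    text = resources.files("careflow").joinpath("data/report_schema.json").read_text()
    return json.loads(text)


def current_schema() -> dict:
    """The JSON schema generated from the pydantic models."""
    return AnalysisReport.model_json_schema()
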