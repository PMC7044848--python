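"""Hub/bottleneck classification of wards.

A node is a **hub** if its degree is at or above the empirical
``quantile`` (default 0.80, i.e. the top 20%) of degrees, and a
**bottleneck** if its betweenness centrality is at or above the same
quantile of betweenness.  Ties at the threshold are included — the
classification is rank-based, so it is invariant to any order-preserving
transform of either metric.  The four-way category is the conjunction of
the two flags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

CATEGORIES = (
    "hub_bottleneck",
    "hub_non_bottleneck",
    "non_hub_bottleneck",
    "neither",
)


@dataclass
class HubBottleneckTable:
    table: pd.DataFrame  # columns: is_hub, is_bottleneck, category
    hub_threshold_value: float
    bottleneck_threshold_value: float
    quantile: float
    hub_metric: str = "k"

    def to_records(self) -> list[dict]:
        return [
            {
                "node": str(node),
                "is_hub": bool(row.is_hub),
                "is_bottleneck": bool(row.is_bottleneck),
                "category": row.category,
            }
            for node, row in self.table.iterrows()
        ]

    @property
    def hubs(self) -> list[str]:
        return [str(n) for n in self.table.index[self.table["is_hub"]]]

    @property
    def bottlenecks(self) -> list[str]:
        return [str(n) for n in self.table.index[self.table["is_bottleneck"]]]


def classify_hubs_bottlenecks(
    metrics: pd.DataFrame,
    quantile: float = 0.80,
    hub_metric: str = "k",
) -> HubBottleneckTable:
    """Classify every node as hub/bottleneck/both/neither.

    ``hub_metric`` is ``"k"`` (unweighted degree, the default) or
    ``"s"`` (strength) as a sensitivity analysis.  Emits a warning — but
    still a classification — when degrees are (nearly) constant and the
    cut degenerates to all-or-nothing.
    """
    if not 0 < quantile < 1:
        raise InvalidParameterError("quantile must lie strictly in (0, 1)")
    if hub_metric not in ("k", "s"):
        raise InvalidParameterError("hub_metric must be 'k' or 's'")
    k = metrics[hub_metric].to_numpy(dtype=float)
    b = metrics["b"].to_numpy(dtype=float)
    if len(k) == 0:
        raise InvalidParameterError("empty metrics table")
    if len(np.unique(k)) < 2:
        warnings.warn(
            "fewer than 2 distinct degree values; hub cut is degenerate",
            stacklevel=2,
        )
    hub_thr = float(np.quantile(k, quantile))
    btl_thr = float(np.quantile(b, quantile))
    is_hub = k >= hub_thr
    is_btl = b >= btl_thr
    category = np.where(
        is_hub & is_btl,
        "hub_bottleneck",
        np.where(
            is_hub, "hub_non_bottleneck", np.where(is_btl, "non_hub_bottleneck", "neither")
        ),
    )
    table = pd.DataFrame(
        {"is_hub": is_hub, "is_bottleneck": is_btl, "category": category},
        index=metrics.index,
    )
    return HubBottleneckTable(
        table=table,
        hub_threshold_value=hub_thr,
        bottleneck_threshold_value=btl_thr,
        quantile=quantile,
        hub_metric=hub_metric,
    )
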