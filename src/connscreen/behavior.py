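"""Correlating screened-edge connectivity strength with behavior.

For each screened edge, the per-animal Fisher-z connectivity values are
correlated (Pearson) with a behavioral metric across animals — both groups
pooled by default, so the correlation spans the treatment-induced spread.
Correlation magnitudes are labeled on the Evans scale (negligible < 0.2,
weak < 0.4, moderate < 0.6, strong < 0.8, very strong >= 0.8).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EdgeBehaviorResult",
    "edge_behavior_correlation",
    "classify_strength",
    "EVANS_SCALE",
    "load_behavior_table",
]

#: (upper bound on |r|, label); the last band is closed at 1.
EVANS_SCALE = [(0.2, "negligible"), (0.4, "weak"), (0.6, "moderate"),
               (0.8, "strong"), (1.0, "very strong")]


@dataclass
class EdgeBehaviorResult:
    """Pearson correlation between one edge's FC strength and one metric."""

    edge: tuple[str, str]
    metric: str
    r: float
    p: float
    n: int
    strength: str


def load_behavior_table(path) -> pd.DataFrame:
    """Read a long-format behavior table (animal_id, metric, value)."""
    df = pd.read_csv(path)
    required = {"animal_id", "metric", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"behavior table needs columns {sorted(required)}")
    return df


def edge_behavior_correlation(edge_values: pd.Series, behavior: pd.Series,
                              edge: tuple[str, str] = ("", ""),
                              metric: str = "", scale=None
                              ) -> EdgeBehaviorResult:
    """Correlate per-animal edge z values with a behavioral metric.

    Both series are indexed by animal id; ids must match one-to-one.

    Raises
    ------
    ValueError
        On fewer than 4 paired animals, or mismatched ids (orphans listed).
    """
    edge_values = pd.Series(edge_values)
    behavior = pd.Series(behavior)
    orphans = set(edge_values.index) ^ set(behavior.index)
    if orphans:
        raise ValueError(f"animal ids do not match; orphans: {sorted(orphans)}")
    behavior = behavior.loc[edge_values.index]
    if len(edge_values) < 4:
        raise ValueError("need at least 4 paired observations")
    r, p = stats.pearsonr(edge_values.to_numpy(dtype=float),
                          behavior.to_numpy(dtype=float))
    return EdgeBehaviorResult(edge=edge, metric=metric, r=float(r), p=float(p),
                              n=len(edge_values),
                              strength=classify_strength(r, scale))


def classify_strength(r: float, scale=None) -> str:
    """Label |r| on the configured band scale (Evans by default)."""
    if not -1 <= r <= 1:
        raise ValueError("|r| must be <= 1")
    scale = scale or EVANS_SCALE
    mag = abs(r)
    for upper, label in scale:
        if mag < upper:
            return label
    return scale[-1][1]


def screen_behavior_table(z_by_animal: pd.DataFrame, behavior: pd.DataFrame,
                          edges: list[tuple[str, str]]) -> pd.DataFrame:
    """Correlate every screened edge with every behavioral metric.

    ``z_by_animal`` has a MultiIndex or tuple-of-str columns per edge and one
    row per animal; ``behavior`` is long format (animal_id, metric, value).
    """
    rows = []
    for metric, sub in behavior.groupby("metric"):
        series = sub.set_index("animal_id")["value"]
        for edge in edges:
            res = edge_behavior_correlation(
                z_by_animal[edge], series.loc[z_by_animal.index],
                edge=edge, metric=str(metric))
            rows.append({"roi_i": edge[0], "roi_j": edge[1], "metric": metric,
                         "r": res.r, "p": res.p, "n": res.n,
                         "strength": res.strength})
    return pd.DataFrame(rows)
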