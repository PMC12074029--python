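"""Node Modulation Index (NMI).

The NMI summarises how strongly a brain region's connectivity is modulated
between groups: for each ROI, rank its connections by effect-size magnitude
|D| and average the signed Cohen's D over the top ``fraction`` (default the
top 10%, with k = ceil(fraction * (n_rois - 1)) so k >= 1).  ROIs are then
ranked by |NMI| descending.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["NMIResult", "node_modulation_index", "rank_rois"]


@dataclass
class NMIResult:
    """Per-ROI node modulation index with contributing edges and ranking."""

    nmi: pd.Series  # indexed by ROI name
    contributing: dict[str, list[str]]  # ROI -> partner ROIs used
    fraction: float
    absolute: bool
    ranking: list[str]

    def to_frame(self) -> pd.DataFrame:
        rank = {roi: i + 1 for i, roi in enumerate(self.ranking)}
        return pd.DataFrame({
            "roi": self.nmi.index,
            "nmi": self.nmi.to_numpy(),
            "rank": [rank[r] for r in self.nmi.index],
            "contributing": [",".join(self.contributing[r]) for r in self.nmi.index],
        })


def node_modulation_index(d: np.ndarray, roi_names: Sequence[str] | None = None,
                          fraction: float = 0.10, absolute: bool = False
                          ) -> NMIResult:
    """Compute the NMI from a symmetric effect-size matrix.

    Parameters
    ----------
    d : (n, n) array
        Symmetric Cohen's-D matrix, diagonal masked (NaN or ignored).
        Masked off-diagonal entries are excluded from the ranking.
    fraction : float
        Fraction of each ROI's n-1 connections to average,
        k = ceil(fraction * (n - 1)).
    absolute : bool
        Average |D| instead of signed D.

    Ties in |D| are broken toward the smaller partner index, making the
    contributing set deterministic.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("effect-size matrix must be square")
    off = ~np.eye(d.shape[0], dtype=bool)
    if not np.allclose(np.where(off, d, 0.0), np.where(off, d.T, 0.0),
                       equal_nan=True):
        raise ValueError("effect-size matrix must be symmetric")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = d.shape[0]
    if roi_names is None:
        roi_names = [f"ROI{i + 1:02d}" for i in range(n)]
    roi_names = list(roi_names)
    k = math.ceil(fraction * (n - 1))

    values = np.empty(n)
    contributing: dict[str, list[str]] = {}
    for i in range(n):
        partners = [j for j in range(n)
                    if j != i and np.isfinite(d[i, j])]
        if not partners:
            raise ValueError(f"all connections of ROI {roi_names[i]} are masked")
        order = sorted(partners, key=lambda j: (-abs(d[i, j]), j))
        top = order[:min(k, len(order))]
        vals = np.abs(d[i, top]) if absolute else d[i, top]
        values[i] = float(np.mean(vals))
        contributing[roi_names[i]] = [roi_names[j] for j in top]

    series = pd.Series(values, index=roi_names, name="nmi")
    return NMIResult(nmi=series, contributing=contributing, fraction=fraction,
                     absolute=absolute, ranking=rank_rois(series))


def rank_rois(nmi: pd.Series | NMIResult) -> list[str]:
    """ROIs ordered by |NMI| descending; ties broken alphabetically."""
    series = nmi.nmi if isinstance(nmi, NMIResult) else nmi
    return sorted(series.index, key=lambda roi: (-abs(series[roi]), roi))
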