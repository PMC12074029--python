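"""ROI-to-ROI functional connectivity matrices.

Per-animal connectivity is the Pearson correlation between every pair of
ROI-averaged time series, giving a symmetric ``n_rois x n_rois`` matrix with
unit diagonal.  Matrices are Fisher-z transformed (z = atanh r) for group
averaging and edge-wise statistics, and converted back to r for display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FCMatrix",
    "pearson_fc",
    "fisher_z",
    "inverse_fisher_z",
    "group_mean_fc",
    "load_timeseries",
]

#: correlations with |r| >= 1 - Z_CLIP_EPS are clipped before atanh so that
#: z stays finite; the induced bias is far below sampling noise.
Z_CLIP_EPS = 1e-7


@dataclass
class FCMatrix:
    """Square connectivity matrix tagged with its value domain.

    ``domain`` is ``"r"`` (Pearson correlations, unit diagonal) or ``"z"``
    (Fisher-z values, diagonal masked to NaN).
    """

    values: np.ndarray
    domain: str
    roi_names: tuple[str, ...]
    tag: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if len(self.roi_names) != v.shape[0]:
            raise ValueError("roi_names length must match matrix size")
        if self.domain not in ("r", "z"):
            raise ValueError(f"unknown domain {self.domain!r}")
        off = v[~np.eye(v.shape[0], dtype=bool)]
        if self.domain == "r" and np.nanmax(np.abs(off), initial=0.0) > 1 + 1e-12:
            raise ValueError("r-domain values must lie in [-1, 1]")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.roi_names, columns=self.roi_names)


def load_timeseries(path) -> pd.DataFrame:
    """Read a delimited per-animal time-series table (header = ROI names)."""
    df = pd.read_csv(path)
    if df.isna().any().any():
        raise ValueError(f"missing values in time series {path}")
    return df


def pearson_fc(ts, roi_names: Sequence[str] | None = None, tag: str = "") -> FCMatrix:
    """Pearson correlation matrix of ROI time series.

    Parameters
    ----------
    ts : DataFrame or (n_volumes, n_rois) array
        One column per ROI, one row per volume.

    Raises
    ------
    ValueError
        If fewer than 3 volumes, or any ROI column has zero variance
        (the offending ROI is named).
    """
    if isinstance(ts, pd.DataFrame):
        if roi_names is None:
            roi_names = tuple(map(str, ts.columns))
        ts = ts.to_numpy(dtype=float)
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time series must be 2-D (volumes x ROIs)")
    if ts.shape[0] < 3:
        raise ValueError("need at least 3 volumes")
    if np.isnan(ts).any():
        raise ValueError("time series contains missing values")
    if roi_names is None:
        roi_names = tuple(f"ROI{i + 1:02d}" for i in range(ts.shape[1]))
    sd = ts.std(axis=0)
    if np.any(sd == 0):
        bad = [roi_names[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance ROI time series: {bad}")
    r = np.corrcoef(ts, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return FCMatrix(r, "r", tuple(roi_names), tag=tag)


def fisher_z(fc: FCMatrix) -> FCMatrix:
    """Fisher-z transform, z = atanh(r), with the diagonal masked to NaN."""
    if fc.domain != "r":
        raise ValueError("fisher_z expects an r-domain matrix")
    r = np.clip(fc.values, -1 + Z_CLIP_EPS, 1 - Z_CLIP_EPS)
    z = np.arctanh(r)
    np.fill_diagonal(z, np.nan)
    return replace(fc, values=z, domain="z")


def inverse_fisher_z(fc: FCMatrix) -> FCMatrix:
    """Back-transform z to r via tanh; the diagonal is restored to 1."""
    if fc.domain != "z":
        raise ValueError("inverse_fisher_z expects a z-domain matrix")
    r = np.tanh(fc.values)
    np.fill_diagonal(r, 1.0)
    return replace(fc, values=r, domain="r")


def group_mean_fc(matrices: Sequence[FCMatrix], average_domain: str = "z",
                  tag: str = "") -> FCMatrix:
    """Group-average connectivity matrix.

    By default individual matrices are averaged in the Fisher-z domain
    (variance-stabilized) and the mean converted back to r.  Set
    ``average_domain="r"`` to average raw correlations instead.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    shapes = {m.values.shape for m in matrices}
    names = {m.roi_names for m in matrices}
    if len(shapes) > 1 or len(names) > 1:
        raise ValueError("matrices must share shape and ROI set")
    if average_domain not in ("z", "r"):
        raise ValueError(f"unknown averaging domain {average_domain!r}")
    mats = [m if m.domain == "r" else inverse_fisher_z(m) for m in matrices]
    if average_domain == "r":
        mean_r = np.mean([m.values for m in mats], axis=0)
        np.fill_diagonal(mean_r, 1.0)
        return FCMatrix(mean_r, "r", mats[0].roi_names, tag=tag)
    zs = np.stack([fisher_z(m).values for m in mats])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN diagonal
        mean_z = np.nanmean(zs, axis=0)
    out = FCMatrix(np.zeros_like(mean_z), "z", mats[0].roi_names, tag=tag)
    out.values = mean_z
    return inverse_fisher_z(out)
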