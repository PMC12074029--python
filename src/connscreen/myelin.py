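"""g-ratio myelin morphometry.

The g-ratio is the inner (axonal) diameter divided by the outer diameter of
the fiber including its myelin sheath; lower g means thicker myelin.  Inner
and outer contours segmented upstream may be supplied as areas (nm^2), which
are converted to circular-equivalent diameters d = 2*sqrt(A/pi).  Axons are
stratified on inner diameter at 400 nm and the groups compared per stratum
with a two-sample t-test; the g-ratio vs diameter relationship is summarised
by an OLS trend per group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "circ_equiv_diameter",
    "g_ratio",
    "GRatioModel",
    "GRatioResults",
    "stratified_compare",
    "gratio_diameter_trend",
    "load_axon_table",
]


def circ_equiv_diameter(area):
    """Diameter of the circle with the given area: d = 2*sqrt(A/pi)."""
    area = np.asarray(area, dtype=float)
    if np.any(area < 0):
        raise ValueError("area must be non-negative")
    return 2.0 * np.sqrt(area / np.pi)


def g_ratio(d_inner, d_outer):
    """Element-wise g = d_inner / d_outer, requiring 0 < inner < outer."""
    d_inner = np.asarray(d_inner, dtype=float)
    d_outer = np.asarray(d_outer, dtype=float)
    if np.any(d_inner <= 0) or np.any(d_outer <= 0):
        raise ValueError("diameters must be positive")
    bad = d_inner >= d_outer
    if np.any(bad):
        raise ValueError(f"{int(np.sum(bad))} row(s) with inner >= outer diameter")
    return d_inner / d_outer


def load_axon_table(path) -> pd.DataFrame:
    """Read a delimited axon table into the canonical diameter form.

    Accepts columns (group, inner_nm, outer_nm) or (group, inner_area_nm2,
    outer_area_nm2); areas are converted to circular-equivalent diameters.
    An optional ``region`` column is carried through.
    """
    df = pd.read_csv(path)
    if {"inner_area_nm2", "outer_area_nm2"}.issubset(df.columns):
        df = df.assign(inner_nm=circ_equiv_diameter(df["inner_area_nm2"]),
                       outer_nm=circ_equiv_diameter(df["outer_area_nm2"]))
    if not {"group", "inner_nm", "outer_nm"}.issubset(df.columns):
        raise ValueError("axon table needs group and inner/outer diameters or areas")
    return df


class GRatioModel:
    """g-ratio morphometry comparing two groups of axons.

    Parameters
    ----------
    table : DataFrame
        Columns ``group``, ``inner_nm``, ``outer_nm`` (one row per axon).
        Rows violating inner < outer are dropped with a warning (their count
        is recorded on the results).
    treated, control : str
        Group labels; by convention the difference and t statistic are
        treated minus control.
    """

    def __init__(self, table: pd.DataFrame, treated: str, control: str):
        table = table.copy()
        missing = {treated, control} - set(table["group"].unique())
        if missing:
            raise ValueError(f"groups not present in table: {sorted(missing)}")
        table = table[table["group"].isin([treated, control])]
        bad = ~(table["inner_nm"] < table["outer_nm"]) | (table["inner_nm"] <= 0)
        self.n_rejected = int(bad.sum())
        if self.n_rejected:
            warnings.warn(f"rejected {self.n_rejected} axon row(s) with "
                          "inner >= outer diameter", RuntimeWarning, stacklevel=2)
        table = table[~bad]
        table = table.assign(g=table["inner_nm"] / table["outer_nm"])
        self.table = table
        self.treated = treated
        self.control = control

    def fit(self, threshold_nm: float = 400.0) -> "GRatioResults":
        strata = stratified_compare(self.table, self.treated, self.control,
                                    threshold_nm=threshold_nm)
        trends = {}
        for grp in (self.treated, self.control):
            sub = self.table[self.table["group"] == grp]
            if len(sub) >= 3 and sub["inner_nm"].var() > 0:
                trends[grp] = gratio_diameter_trend(sub)
        return GRatioResults(table=self.table, strata=strata, trends=trends,
                             threshold_nm=threshold_nm, treated=self.treated,
                             control=self.control, n_rejected=self.n_rejected)


@dataclass
class GRatioResults:
    """Stratified group comparison and per-group diameter trends."""

    table: pd.DataFrame
    strata: pd.DataFrame
    trends: dict[str, tuple[float, float]]  # group -> (slope per nm, intercept)
    threshold_nm: float
    treated: str
    control: str
    n_rejected: int

    def summary(self) -> str:
        lines = [
            "g-ratio morphometry",
            "===================",
            f"groups: {self.treated} (treated) vs {self.control} (control); "
            f"{len(self.table)} axons analysed, {self.n_rejected} rejected",
            f"stratified on inner diameter at {self.threshold_nm:g} nm:",
            self.strata.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        ]
        for grp, (slope, intercept) in self.trends.items():
            lines.append(f"trend [{grp}]: g = {slope:.3e} * d_nm + {intercept:.4f}")
        return "\n".join(lines)


def stratified_compare(table: pd.DataFrame, treated: str, control: str,
                       threshold_nm: float = 400.0) -> pd.DataFrame:
    """Two-sample t-test on g per diameter stratum (below / at-or-above).

    Strata with fewer than 2 axons in either group are skipped with a
    warning.  Positive t means higher g in the treated group.
    """
    if "g" not in table.columns:
        table = table.assign(g=g_ratio(table["inner_nm"], table["outer_nm"]))
    rows = []
    for stratum, mask in (("below", table["inner_nm"] < threshold_nm),
                          ("at_or_above", table["inner_nm"] >= threshold_nm)):
        sub = table[mask]
        ga = sub.loc[sub["group"] == treated, "g"].to_numpy()
        gb = sub.loc[sub["group"] == control, "g"].to_numpy()
        if len(ga) < 2 or len(gb) < 2:
            warnings.warn(f"stratum {stratum!r} has too few axons per group; "
                          "skipped", RuntimeWarning, stacklevel=2)
            continue
        t, p = stats.ttest_ind(ga, gb)
        rows.append({"stratum": stratum,
                     "n_treated": len(ga), "n_control": len(gb),
                     "mean_treated": ga.mean(), "mean_control": gb.mean(),
                     "sd_treated": ga.std(ddof=1), "sd_control": gb.std(ddof=1),
                     "delta": ga.mean() - gb.mean(),
                     "t": float(t), "p": float(p)})
    return pd.DataFrame(rows, columns=["stratum", "n_treated", "n_control",
                                       "mean_treated", "mean_control",
                                       "sd_treated", "sd_control", "delta",
                                       "t", "p"])


def gratio_diameter_trend(table: pd.DataFrame) -> tuple[float, float]:
    """OLS of g on inner diameter: returns (slope per nm, intercept)."""
    if "g" not in table.columns:
        table = table.assign(g=g_ratio(table["inner_nm"], table["outer_nm"]))
    if len(table) < 3:
        raise ValueError("need at least 3 axons for a trend")
    d = table["inner_nm"].to_numpy(dtype=float)
    if d.var() == 0:
        raise ValueError("zero diameter variance")
    res = stats.linregress(d, table["g"].to_numpy(dtype=float))
    return float(res.slope), float(res.intercept)
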