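"""Edge-wise group inference on connectivity matrices.

The multi-parameter screen combines two arms computed on Fisher-z edge
values with the animal as the statistical unit:

* a significance arm — per-edge two-sample t-test with multiplicity
  correction (Benjamini–Hochberg FDR by default, Bonferroni optional);
* an effect-size arm — per-edge Cohen's D with a |D| threshold
  (0.8, "large", by default).

:class:`ConnectivityScreen` is the model object; :meth:`ConnectivityScreen.fit`
returns a :class:`ScreenResults` carrying the per-edge table, the Cohen's-D
matrix, the selected edge sets and the node-modulation-index ranking.

Sign convention: group A is the treated group, so positive t and D mean
stronger connectivity under treatment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .fc import FCMatrix, fisher_z
from . import nmi as _nmi

__all__ = [
    "ScreenConfig",
    "ConnectivityScreen",
    "ScreenResults",
    "edgewise_ttest",
    "adjust_pvalues",
    "cohens_d_matrix",
    "screen_edges",
]


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and test variants for the multi-parameter edge screen."""

    alpha: float = 0.01
    correction: str = "bh_fdr"  # or "bonferroni"
    d_threshold: float = 0.8
    test_variant: str = "student"  # or "welch"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.d_threshold <= 0:
            raise ValueError("d_threshold must be positive")
        if self.correction not in ("bh_fdr", "bonferroni"):
            raise ValueError(f"unknown correction {self.correction!r}")
        if self.test_variant not in ("student", "welch"):
            raise ValueError(f"unknown test variant {self.test_variant!r}")


def _edge_stack(matrices: Sequence[FCMatrix]) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple[str, ...]]:
    """Stack z matrices into (n_animals, n_edges) over unordered pairs i<j."""
    zs = []
    names = None
    for m in matrices:
        if m.domain != "z":
            m = fisher_z(m)
        if names is None:
            names = m.roi_names
        elif m.roi_names != names or m.values.shape != zs[0].shape:
            raise ValueError("matrices must share shape and ROI set")
        zs.append(m.values)
    iu, ju = np.triu_indices(len(names), k=1)
    return np.stack(zs)[:, iu, ju], iu, ju, names


def edgewise_ttest(group_a: Sequence[FCMatrix], group_b: Sequence[FCMatrix],
                   variant: str = "student") -> pd.DataFrame:
    """Two-sample t-test per unordered ROI pair on Fisher-z values.

    Returns a DataFrame with one row per edge (i < j): roi_i, roi_j, t, p.
    Edges where both groups are constant and equal get t=0, p=1; constant
    but unequal edges get p=1 with a warning (no variance to test against).
    """
    za, iu, ju, names = _edge_stack(group_a)
    zb, _, _, names_b = _edge_stack(group_b)
    if names != names_b:
        raise ValueError("groups must share the ROI set")
    na, nb = za.shape[0], zb.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 animals per group")

    ma, mb = za.mean(axis=0), zb.mean(axis=0)
    va, vb = za.var(axis=0, ddof=1), zb.var(axis=0, ddof=1)
    diff = ma - mb
    if variant == "student":
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        df = np.full_like(se, na + nb - 2.0)
    elif variant == "welch":
        se = np.sqrt(va / na + vb / nb)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = (va / na + vb / nb) ** 2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
    else:
        raise ValueError(f"unknown test variant {variant!r}")

    t = np.zeros_like(diff)
    p = np.ones_like(diff)
    ok = se > 0
    t[ok] = diff[ok] / se[ok]
    p[ok] = 2 * stats.t.sf(np.abs(t[ok]), df[ok])
    degenerate = (~ok) & (diff != 0)
    if degenerate.any():
        warnings.warn(
            f"{degenerate.sum()} edge(s) with zero pooled variance but unequal "
            "means; p set to 1", RuntimeWarning, stacklevel=2)
    return pd.DataFrame({
        "roi_i": [names[i] for i in iu],
        "roi_j": [names[j] for j in ju],
        "t": t,
        "p": p,
    })


def adjust_pvalues(p, method: str = "bh_fdr") -> np.ndarray:
    """Multiplicity-adjusted p-values (Benjamini–Hochberg or Bonferroni)."""
    p = np.asarray(p, dtype=float)
    if p.size and (np.isnan(p).any() or p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bh_fdr":
        return multipletests(p, method="fdr_bh")[1]
    if method == "bonferroni":
        return np.minimum(1.0, p * p.size)
    raise ValueError(f"unknown correction {method!r}")


def cohens_d_matrix(group_a: Sequence[FCMatrix], group_b: Sequence[FCMatrix]
                    ) -> FCMatrix:
    """Cohen's D per edge: (mean_A - mean_B) / pooled SD over animals.

    Positive D means stronger connectivity in group A (treated).  Edges with
    zero pooled SD are masked to NaN with a warning.  The result is returned
    as a symmetric matrix with NaN diagonal, tagged domain "z" (effect sizes
    live on the Fisher-z scale).
    """
    za, iu, ju, names = _edge_stack(group_a)
    zb, _, _, names_b = _edge_stack(group_b)
    if names != names_b:
        raise ValueError("groups must share the ROI set")
    na, nb = za.shape[0], zb.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 animals per group")
    sp2 = ((na - 1) * za.var(axis=0, ddof=1) + (nb - 1) * zb.var(axis=0, ddof=1)) / (
        na + nb - 2)
    sp = np.sqrt(sp2)
    d = np.full_like(sp, np.nan)
    ok = sp > 0
    d[ok] = (za.mean(axis=0) - zb.mean(axis=0))[ok] / sp[ok]
    if (~ok).any():
        warnings.warn(f"{(~ok).sum()} edge(s) with zero pooled SD; D masked",
                      RuntimeWarning, stacklevel=2)
    n = len(names)
    mat = np.full((n, n), np.nan)
    mat[iu, ju] = d
    mat[ju, iu] = d
    out = FCMatrix(np.zeros((n, n)), "z", names, tag="cohens_d")
    out.values = mat
    return out


@dataclass
class ScreenSets:
    """Selected edge sets from the multi-parameter screen."""

    significance: list[tuple[str, str]]
    effect: list[tuple[str, str]]
    intersection: list[tuple[str, str]]
    enhanced: list[tuple[str, str]]
    reduced: list[tuple[str, str]]


def screen_edges(edges: pd.DataFrame, config: ScreenConfig | None = None
                 ) -> ScreenSets:
    """Apply the significance and effect-size thresholds to an edge table.

    ``edges`` needs columns roi_i, roi_j, p_adj, d (and t for direction).
    Edges with masked (NaN) D are excluded from the effect set but remain
    eligible for the significance set.
    """
    config = config or ScreenConfig()
    pairs = list(zip(edges["roi_i"], edges["roi_j"]))
    sig = edges["p_adj"].to_numpy() < config.alpha
    d = edges["d"].to_numpy(dtype=float)
    eff = np.abs(d) > config.d_threshold
    eff &= ~np.isnan(d)
    direction = np.where(np.isnan(d), edges["t"].to_numpy(), d) > 0
    both = sig & eff
    return ScreenSets(
        significance=[pr for pr, s in zip(pairs, sig) if s],
        effect=[pr for pr, e in zip(pairs, eff) if e],
        intersection=[pr for pr, b in zip(pairs, both) if b],
        enhanced=[pr for pr, b, up in zip(pairs, both, direction) if b and up],
        reduced=[pr for pr, b, up in zip(pairs, both, direction) if b and not up],
    )


class ConnectivityScreen:
    """Multi-parameter edge screen between two groups of animals.

    Parameters
    ----------
    group_a, group_b : sequences of FCMatrix
        Per-animal connectivity matrices (r or z domain; r is transformed).
        Group A is the treated group by the package's sign convention.
    """

    def __init__(self, group_a: Sequence[FCMatrix], group_b: Sequence[FCMatrix]):
        if len(group_a) < 2 or len(group_b) < 2:
            raise ValueError("need at least 2 animals per group")
        self.group_a = list(group_a)
        self.group_b = list(group_b)

    @classmethod
    def from_cohort(cls, cohort) -> "ConnectivityScreen":
        """Build from a :class:`~connscreen.synthetic.SyntheticCohort`
        (or any object with ``z_matrices_by_group()``)."""
        by_group = cohort.z_matrices_by_group()
        groups = sorted(by_group)
        if len(groups) != 2:
            raise ValueError("cohort must have exactly two groups")
        return cls(by_group[groups[0]], by_group[groups[1]])

    def fit(self, config: ScreenConfig | None = None) -> "ScreenResults":
        config = config or ScreenConfig()
        edges = edgewise_ttest(self.group_a, self.group_b,
                               variant=config.test_variant)
        edges["p_adj"] = adjust_pvalues(edges["p"].to_numpy(), config.correction)
        d_mat = cohens_d_matrix(self.group_a, self.group_b)
        iu, ju = np.triu_indices(d_mat.n, k=1)
        edges["d"] = d_mat.values[iu, ju]
        sets = screen_edges(edges, config)
        pairs = list(zip(edges["roi_i"], edges["roi_j"]))
        edges["selected_significance"] = [pr in set(sets.significance) for pr in pairs]
        edges["selected_effect"] = [pr in set(sets.effect) for pr in pairs]
        return ScreenResults(edges=edges, d_matrix=d_mat, sets=sets,
                             config=config, n_a=len(self.group_a),
                             n_b=len(self.group_b))


@dataclass
class ScreenResults:
    """Fitted multi-parameter screen: per-edge statistics and selections."""

    edges: pd.DataFrame
    d_matrix: FCMatrix
    sets: ScreenSets
    config: ScreenConfig
    n_a: int
    n_b: int
    _nmi_cache: dict = field(default_factory=dict, repr=False)

    def selected_edges(self, kind: str = "intersection") -> list[tuple[str, str]]:
        """Edge set by arm: significance | effect | intersection."""
        return getattr(self.sets, kind)

    def nmi(self, fraction: float = 0.10, absolute: bool = False):
        """Node Modulation Index computed from the Cohen's-D matrix."""
        key = (fraction, absolute)
        if key not in self._nmi_cache:
            self._nmi_cache[key] = _nmi.node_modulation_index(
                self.d_matrix.values, roi_names=self.d_matrix.roi_names,
                fraction=fraction, absolute=absolute)
        return self._nmi_cache[key]

    def chord_edgelist(self, kind: str = "intersection") -> pd.DataFrame:
        """Edge list (source, target, direction, weight, p_adj) for chord plots."""
        selected = set(self.selected_edges(kind))
        rows = []
        for _, row in self.edges.iterrows():
            pair = (row["roi_i"], row["roi_j"])
            if pair not in selected:
                continue
            up = (row["d"] if np.isfinite(row["d"]) else row["t"]) > 0
            rows.append({
                "source": pair[0], "target": pair[1],
                "direction": "enhanced" if up else "reduced",
                "weight": abs(row["d"]),
                "p_adj": row["p_adj"],
            })
        return pd.DataFrame(rows, columns=["source", "target", "direction",
                                           "weight", "p_adj"])

    def summary(self) -> str:
        """Plain-text summary of the screen."""
        cfg = self.config
        lines = [
            "Multi-parameter connectivity screen",
            "===================================",
            f"groups: A (treated) n={self.n_a}, B (control) n={self.n_b}; "
            f"edges tested: {len(self.edges)}",
            f"test: {cfg.test_variant} t, correction: {cfg.correction}, "
            f"alpha={cfg.alpha}, |D| > {cfg.d_threshold}",
            f"significant edges (p_adj < {cfg.alpha}): {len(self.sets.significance)}",
            f"large-effect edges (|D| > {cfg.d_threshold}): {len(self.sets.effect)}",
            f"multi-parameter intersection: {len(self.sets.intersection)} "
            f"({len(self.sets.enhanced)} enhanced, {len(self.sets.reduced)} reduced)",
        ]
        top = self.edges.reindex(
            self.edges["d"].abs().sort_values(ascending=False).index).head(10)
        lines.append("top edges by |D|:")
        lines.append(top[["roi_i", "roi_j", "t", "p", "p_adj", "d"]]
                     .to_string(index=False, float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)
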