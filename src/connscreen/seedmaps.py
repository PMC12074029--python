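"""Seed-based voxel-wise connectivity maps and group t-maps.

A seed time course is the unweighted mean over the seed-mask voxels; each
in-mask brain voxel is correlated with it (Pearson r), Fisher-z transformed
for group statistics, and groups are compared voxel-wise with a two-sample
t-test (optional voxel-level BH-FDR mask).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .fc import Z_CLIP_EPS
from .screening import adjust_pvalues

__all__ = [
    "VoxelSeries",
    "SeedMap",
    "seed_timecourse",
    "seed_correlation_map",
    "group_seed_tmap",
    "load_nifti_series",
    "save_nifti_map",
]


@dataclass
class VoxelSeries:
    """4-D voxel data (x, y, z, t) with a 3-D brain mask and affine."""

    data: np.ndarray
    brain_mask: np.ndarray | None = None
    affine: np.ndarray | None = None
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("voxel data must be 4-D (x, y, z, t)")
        if self.data.shape[3] < 3:
            raise ValueError("need at least 3 timepoints")
        if self.brain_mask is None:
            self.brain_mask = np.ones(self.data.shape[:3], dtype=bool)
        else:
            self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
            if self.brain_mask.shape != self.data.shape[:3]:
                raise ValueError("brain mask shape must match spatial dims")
        if self.affine is None:
            self.affine = np.diag((*self.voxel_size_mm, 1.0))


@dataclass
class SeedMap:
    """3-D map in r, z, t or p domain, defined inside the brain mask."""

    values: np.ndarray
    domain: str  # r | z | t | p
    seed_label: str = ""
    tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("seed map must be 3-D")
        if self.domain not in ("r", "z", "t", "p"):
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.domain == "r":
            finite = self.values[np.isfinite(self.values)]
            if finite.size and np.abs(finite).max() > 1 + 1e-12:
                raise ValueError("r-domain map values must lie in [-1, 1]")


def load_nifti_series(path, mask_path=None) -> VoxelSeries:
    """Read a 4-D NIfTI volume (and optional 3-D mask) into a VoxelSeries."""
    import nibabel as nib

    img = nib.load(str(path))
    mask = None
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    zooms = img.header.get_zooms()[:3]
    return VoxelSeries(np.asarray(img.dataobj, dtype=float), brain_mask=mask,
                       affine=img.affine, voxel_size_mm=tuple(map(float, zooms)))


def save_nifti_map(seed_map: SeedMap, affine: np.ndarray, path) -> None:
    """Write a 3-D map as NIfTI-1."""
    import nibabel as nib

    nib.save(nib.Nifti1Image(seed_map.values.astype(np.float32), affine), str(path))


def seed_timecourse(vol: VoxelSeries, seed_mask: np.ndarray) -> np.ndarray:
    """Unweighted mean time course over the seed voxels."""
    seed_mask = np.asarray(seed_mask, dtype=bool)
    if seed_mask.shape != vol.data.shape[:3]:
        raise ValueError("seed mask shape must match spatial dims")
    if not seed_mask.any():
        raise ValueError("seed mask is empty")
    if (seed_mask & ~vol.brain_mask).any():
        raise ValueError("seed mask must lie inside the brain mask")
    return vol.data[seed_mask].mean(axis=0)


def seed_correlation_map(vol: VoxelSeries, seed_series: np.ndarray,
                         seed_label: str = "", domain: str = "r") -> SeedMap:
    """Pearson correlation of every in-mask voxel with the seed series.

    Zero-variance voxels and out-of-mask voxels are NaN.  ``domain="z"``
    returns the Fisher-z map used for group statistics.
    """
    seed_series = np.asarray(seed_series, dtype=float)
    if seed_series.shape != (vol.data.shape[3],):
        raise ValueError("seed series length must equal the number of timepoints")
    if seed_series.std() == 0:
        raise ValueError("constant seed series")
    mask = vol.brain_mask
    x = vol.data[mask]  # (n_vox, t)
    xc = x - x.mean(axis=1, keepdims=True)
    sc = seed_series - seed_series.mean()
    xn = np.sqrt((xc ** 2).sum(axis=1))
    sn = np.sqrt((sc ** 2).sum())
    r = np.full(x.shape[0], np.nan)
    ok = xn > 0
    r[ok] = (xc[ok] @ sc) / (xn[ok] * sn)
    r = np.clip(r, -1.0, 1.0)
    out = np.full(vol.data.shape[:3], np.nan)
    out[mask] = r
    m = SeedMap(out, "r", seed_label=seed_label)
    return fisher_z_map(m) if domain == "z" else m


def fisher_z_map(m: SeedMap) -> SeedMap:
    if m.domain != "r":
        raise ValueError("expected an r-domain map")
    z = np.arctanh(np.clip(m.values, -1 + Z_CLIP_EPS, 1 - Z_CLIP_EPS))
    return replace(m, values=z, domain="z")


def group_seed_tmap(maps_a: Sequence[SeedMap], maps_b: Sequence[SeedMap],
                    fdr_alpha: float | None = None
                    ) -> tuple[SeedMap, SeedMap, np.ndarray | None]:
    """Voxel-wise two-sample t-map (A - B) on z-domain seed maps.

    Returns (t map, p map, suprathreshold mask or None).  The mask is the
    voxel-level BH-FDR selection at ``fdr_alpha`` if given.
    """
    if len(maps_a) < 2 or len(maps_b) < 2:
        raise ValueError("need at least 2 maps per group")
    shapes = {m.values.shape for m in [*maps_a, *maps_b]}
    if len(shapes) > 1:
        raise ValueError("seed-map grids do not match")
    if any(m.domain != "z" for m in [*maps_a, *maps_b]):
        raise ValueError("group t-maps are computed on z-domain maps")
    za = np.stack([m.values for m in maps_a])
    zb = np.stack([m.values for m in maps_b])
    valid = np.isfinite(za).all(axis=0) & np.isfinite(zb).all(axis=0)
    na, nb = za.shape[0], zb.shape[0]
    ma, mb = za.mean(axis=0), zb.mean(axis=0)
    va = za.var(axis=0, ddof=1)
    vb = zb.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    # zero between-animal variance (e.g. voxels inside the seed itself)
    # leaves nothing to test against
    valid &= np.nan_to_num(sp2) > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    t[~valid] = np.nan
    p = np.full_like(t, np.nan)
    p[valid] = 2 * stats.t.sf(np.abs(t[valid]), na + nb - 2)
    mask = None
    if fdr_alpha is not None:
        p_adj = np.full_like(p, np.nan)
        p_adj[valid] = adjust_pvalues(p[valid], "bh_fdr")
        mask = np.zeros_like(valid)
        mask[valid] = p_adj[valid] < fdr_alpha
    label = maps_a[0].seed_label
    return (SeedMap(t, "t", seed_label=label),
            SeedMap(p, "p", seed_label=label), mask)
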