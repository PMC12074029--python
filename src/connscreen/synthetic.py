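"""Synthetic cohorts with planted effects of known size.

Every input kind the pipeline consumes can be generated here with a
recoverable ground truth:

* ROI time-series cohorts with group differences planted on chosen edges.
  Effects are defined in Fisher-z space: a target Cohen's D on an edge is
  converted to two group-mean z values via ``z_A - z_B = d * sigma_z``,
  where ``sigma_z`` is the between-animal z spread, so the target D is
  exact by construction as animal and volume counts grow.  Each animal
  draws its own edge z around its group mean (two-level noise: between- and
  within-animal), then a multivariate-normal time series matching that
  animal's correlation matrix.
* 4-D voxel volumes with a planted region sharing a latent signal with a
  seed at a target correlation.
* EMG traces as band-limited Gaussian noise per frequency band (power
  proportional to gain^2) plus a mains sinusoid, with a wake/sleep label
  track.
* Axon tables with a g-ratio shift planted only below a diameter threshold
  in the treated group.
* Binary fiber images rasterized from random smooth curves with analytic
  length and crossing-count ground truth.

One integer seed drives everything; sub-generators derive child seeds
deterministically, so identical spec + seed reproduces outputs bit for bit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .emg import SignalRecording
from .fc import FCMatrix, fisher_z, pearson_fc
from .seedmaps import VoxelSeries

__all__ = [
    "CohortSpec", "SyntheticCohort", "simulate_fc_cohort",
    "simulate_voxel_volume", "VoxelSim",
    "EMGSpec", "simulate_emg", "simulate_emg_group",
    "AxonPopulationSpec", "simulate_axons",
    "simulate_fiber_image",
    "write_cohort",
]


# ---------------------------------------------------------------- FC cohorts

@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a two-group ROI time-series cohort.

    Defaults mirror the profiled study: 31 ROIs, 300 volumes at 1 s
    sampling, 9 treated and 8 control animals.  ``sigma_z`` (default 0.15)
    is the between-animal SD of edge z values; planted effects are
    ``(roi_i, roi_j, target_cohens_d)`` with D defined on the z scale.
    """

    n_rois: int = 31
    n_volumes: int = 300
    n_group_a: int = 9
    n_group_b: int = 8
    baseline_corr: float = 0.1
    planted_edges: tuple[tuple[int, int, float], ...] = ()
    behavior_coupling: tuple[tuple[tuple[int, int], str, float], ...] = ()
    sigma_z: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_rois", "n_volumes", "n_group_a", "n_group_b"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if not -1 < self.baseline_corr < 1:
            raise ValueError("baseline_corr must lie in (-1, 1)")
        if self.sigma_z <= 0:
            raise ValueError("sigma_z must be positive")
        seen = set()
        for i, j, _ in self.planted_edges:
            if i == j or not (0 <= i < self.n_rois and 0 <= j < self.n_rois):
                raise ValueError(f"invalid planted edge ({i}, {j})")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate planted edge {key}")
            seen.add(key)
        for _, _, rho in self.behavior_coupling:
            if not -1 < rho < 1:
                raise ValueError("behavior coupling |rho| must be < 1")


@dataclass
class SyntheticCohort:
    """Generated cohort: per-animal time series, labels, behavior, truth."""

    timeseries: dict[str, np.ndarray]  # animal_id -> (n_volumes, n_rois)
    groups: dict[str, str]  # animal_id -> "A" (treated) | "B"
    roi_names: tuple[str, ...]
    behavior: pd.DataFrame  # long: animal_id, metric, value
    truth: dict

    def fc_matrices(self) -> dict[str, FCMatrix]:
        return {aid: pearson_fc(ts, self.roi_names, tag=aid)
                for aid, ts in self.timeseries.items()}

    def z_matrices_by_group(self) -> dict[str, list[FCMatrix]]:
        out: dict[str, list[FCMatrix]] = {}
        for aid, ts in self.timeseries.items():
            out.setdefault(self.groups[aid], []).append(
                fisher_z(pearson_fc(ts, self.roi_names, tag=aid)))
        return out

    def edge_z_frame(self, edges: list[tuple[str, str]]) -> pd.DataFrame:
        """Per-animal Fisher-z values for the named edges (animals as rows)."""
        name_idx = {n: k for k, n in enumerate(self.roi_names)}
        rows = {}
        for aid, ts in self.timeseries.items():
            z = fisher_z(pearson_fc(ts, self.roi_names)).values
            rows[aid] = [z[name_idx[i], name_idx[j]] for i, j in edges]
        return pd.DataFrame.from_dict(rows, orient="index", columns=edges)


def simulate_fc_cohort(spec: CohortSpec,
                       roi_names: tuple[str, ...] | None = None
                       ) -> SyntheticCohort:
    """Generate a two-group cohort with effects planted in Fisher-z space.

    Raises
    ------
    ValueError
        If an animal's correlation matrix is not positive definite; the
        message reports the planted edge(s) driving the failure.
    """
    if roi_names is None:
        roi_names = tuple(f"ROI{i + 1:02d}" for i in range(spec.n_rois))
    if len(roi_names) != spec.n_rois:
        raise ValueError("roi_names length must equal n_rois")

    ss = np.random.SeedSequence(spec.seed)
    n_animals = spec.n_group_a + spec.n_group_b
    children = ss.spawn(n_animals + 1)
    z0 = math.atanh(spec.baseline_corr)

    ids = ([f"A{k + 1:02d}" for k in range(spec.n_group_a)]
           + [f"B{k + 1:02d}" for k in range(spec.n_group_b)])
    groups = {aid: aid[0] for aid in ids}

    timeseries: dict[str, np.ndarray] = {}
    animal_edge_z: dict[str, dict[tuple[int, int], float]] = {}
    for aid, child in zip(ids, children):
        rng = np.random.default_rng(child)
        corr = np.full((spec.n_rois, spec.n_rois), spec.baseline_corr)
        np.fill_diagonal(corr, 1.0)
        edge_z = {}
        for i, j, d in spec.planted_edges:
            half = d * spec.sigma_z / 2.0
            mean_z = z0 + (half if groups[aid] == "A" else -half)
            z_ij = rng.normal(mean_z, spec.sigma_z)
            corr[i, j] = corr[j, i] = math.tanh(z_ij)
            edge_z[(min(i, j), max(i, j))] = z_ij
        try:
            chol = np.linalg.cholesky(corr)
        except np.linalg.LinAlgError:
            edges = sorted(edge_z, key=lambda e: -abs(corr[e[0], e[1]]))
            raise ValueError(
                f"correlation matrix for animal {aid} is not positive "
                f"definite; planted edges by |r|: {edges}") from None
        timeseries[aid] = rng.standard_normal((spec.n_volumes, spec.n_rois)) @ chol.T
        animal_edge_z[aid] = edge_z

    behavior = _behavior_table(spec, ids, animal_edge_z,
                               np.random.default_rng(children[-1]))
    truth = {
        "planted_edges": [
            {"roi_i": roi_names[min(i, j)], "roi_j": roi_names[max(i, j)],
             "i": int(min(i, j)), "j": int(max(i, j)),
             "target_d": float(d)}
            for i, j, d in spec.planted_edges],
        "sigma_z": spec.sigma_z,
        "baseline_corr": spec.baseline_corr,
        "seed": spec.seed,
    }
    return SyntheticCohort(timeseries=timeseries, groups=groups,
                           roi_names=roi_names, behavior=behavior, truth=truth)


_BEHAVIOR_UNITS = {"hanging_time_s": (60.0, 20.0), "passing_time_s": (10.0, 3.0)}


def _behavior_table(spec, ids, animal_edge_z, rng) -> pd.DataFrame:
    rows = []
    coupling = list(spec.behavior_coupling)
    if not coupling:
        for metric in _BEHAVIOR_UNITS:
            mu, sd = _BEHAVIOR_UNITS[metric]
            for aid in ids:
                rows.append({"animal_id": aid, "metric": metric,
                             "value": max(0.0, rng.normal(mu, sd))})
        return pd.DataFrame(rows)
    for (i, j), metric, rho in coupling:
        key = (min(i, j), max(i, j))
        z = np.array([animal_edge_z[aid].get(key, 0.0) for aid in ids])
        if z.std() > 0:
            zstd = (z - z.mean()) / z.std()
        else:
            zstd = np.zeros_like(z)
        latent = rho * zstd + math.sqrt(1 - rho ** 2) * rng.standard_normal(len(ids))
        mu, sd = _BEHAVIOR_UNITS.get(metric, (0.0, 1.0))
        for aid, v in zip(ids, mu + sd * latent):
            rows.append({"animal_id": aid, "metric": metric, "value": float(v)})
    return pd.DataFrame(rows)


# ------------------------------------------------------------- voxel volumes

@dataclass
class VoxelSim:
    """A simulated 4-D volume with its masks and planted truth."""

    volume: VoxelSeries
    seed_mask: np.ndarray
    region_mask: np.ndarray
    truth: dict


def simulate_voxel_volume(n_xyz: tuple[int, int, int] = (20, 20, 20),
                          n_volumes: int = 300,
                          seed_mask: np.ndarray | None = None,
                          region_mask: np.ndarray | None = None,
                          target_corr: float = 0.8,
                          seed: int = 0,
                          allow_overlap: bool = False) -> VoxelSim:
    """Simulate a volume whose planted region tracks the seed at target r.

    Seed voxels carry the latent signal; region voxels mix it at
    ``target_corr``; all other voxels are independent noise.
    """
    if not -1 < target_corr < 1:
        raise ValueError("|target_corr| must be < 1")
    shape = tuple(n_xyz)
    if seed_mask is None:
        seed_mask = np.zeros(shape, dtype=bool)
        c = tuple(s // 4 for s in shape)
        seed_mask[c[0]:c[0] + 2, c[1]:c[1] + 2, c[2]:c[2] + 2] = True
    if region_mask is None:
        region_mask = np.zeros(shape, dtype=bool)
        c = tuple(2 * s // 3 for s in shape)
        region_mask[c[0]:c[0] + 4, c[1]:c[1] + 4, c[2]:c[2] + 4] = True
    seed_mask = np.asarray(seed_mask, dtype=bool)
    region_mask = np.asarray(region_mask, dtype=bool)
    if seed_mask.shape != shape or region_mask.shape != shape:
        raise ValueError("masks must match the grid shape")
    if (seed_mask & region_mask).any() and not allow_overlap:
        raise ValueError("seed and planted region masks overlap "
                         "(pass allow_overlap=True if intended)")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    latent = rng.standard_normal(n_volumes)
    data = rng.standard_normal((*shape, n_volumes))
    mix = math.sqrt(1 - target_corr ** 2)
    data[region_mask] = target_corr * latent + mix * data[region_mask]
    data[seed_mask] = latent
    vol = VoxelSeries(data)
    return VoxelSim(volume=vol, seed_mask=seed_mask, region_mask=region_mask,
                    truth={"target_corr": target_corr, "seed": seed})


# ----------------------------------------------------------------------- EMG

@dataclass(frozen=True)
class EMGSpec:
    """Synthetic EMG recording conditions.

    The signal is a sum of band-limited unit-variance Gaussian noise scaled
    by each band's linear gain (band power proportional to gain^2) plus a
    mains sinusoid; sleep-labeled samples are attenuated to emulate muscle
    atonia.
    """

    fs: float = 1000.0
    duration_s: float = 300.0
    band_gains: tuple[tuple[tuple[float, float], float], ...] = (
        ((1.0, 20.0), 0.5), ((20.0, 50.0), 1.0), ((50.0, 150.0), 1.0))
    mains_hz: float = 50.0
    mains_amp: float = 0.1
    wake_fraction: float = 0.5
    sleep_attenuation: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("fs and duration must be positive")
        if not 0 < self.wake_fraction <= 1:
            raise ValueError("wake_fraction must be in (0, 1]")
        for (lo, hi), _ in self.band_gains:
            if not 0 < lo < hi < self.fs / 2:
                raise ValueError(f"band ({lo}, {hi}) must lie inside (0, Nyquist)")
        lo_min = min(lo for (lo, _), _ in self.band_gains)
        if self.duration_s < 2.0 / lo_min:
            raise ValueError("duration too short for the lowest band "
                             "(need at least 2 cycles)")


def simulate_emg(spec: EMGSpec, animal_id: str = "", group: str = "",
                 gain_scale: dict[tuple[float, float], float] | None = None
                 ) -> SignalRecording:
    """Generate one labeled EMG trace per the spec.

    ``gain_scale`` multiplies selected bands' gains (used to plant group
    effects without changing the base conditions).
    """
    n = int(round(spec.duration_s * spec.fs))
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    x = np.zeros(n)
    for (lo, hi), gain in spec.band_gains:
        if gain_scale:
            gain = gain * gain_scale.get((lo, hi), 1.0)
        if gain == 0:
            continue
        sos = _signal.butter(4, (lo, hi), btype="bandpass", fs=spec.fs,
                             output="sos")
        noise = _signal.sosfiltfilt(sos, rng.standard_normal(n))
        sd = noise.std()
        if sd > 0:
            x += gain * noise / sd
    if spec.mains_amp:
        t = np.arange(n) / spec.fs
        x += spec.mains_amp * np.sin(2 * np.pi * spec.mains_hz * t)
    labels = np.zeros(n, dtype=bool)
    labels[: int(round(spec.wake_fraction * n))] = True
    x[~labels] *= spec.sleep_attenuation
    return SignalRecording(samples=x, fs=spec.fs, labels=labels,
                           animal_id=animal_id, group=group)


def simulate_emg_group(spec: EMGSpec, n_animals: int, group: str,
                       gain_scale: dict[tuple[float, float], float] | None = None,
                       animal_gain_log_sd: float = 0.2,
                       seed: int | None = None) -> list[SignalRecording]:
    """A group of EMG recordings with lognormal between-animal gain jitter."""
    if n_animals < 1:
        raise ValueError("need at least one animal")
    ss = np.random.SeedSequence(spec.seed if seed is None else seed)
    children = ss.spawn(n_animals)
    recs = []
    for k, child in enumerate(children):
        rng = np.random.default_rng(child)
        jitter = {band: math.exp(rng.normal(0.0, animal_gain_log_sd))
                  for (band, _) in spec.band_gains}
        scale = {band: jitter[band] * (gain_scale or {}).get(band, 1.0)
                 for band in jitter}
        sub = int(rng.integers(0, 2 ** 31 - 1))
        rec_spec = EMGSpec(fs=spec.fs, duration_s=spec.duration_s,
                           band_gains=spec.band_gains, mains_hz=spec.mains_hz,
                           mains_amp=spec.mains_amp,
                           wake_fraction=spec.wake_fraction,
                           sleep_attenuation=spec.sleep_attenuation, seed=sub)
        recs.append(simulate_emg(rec_spec, animal_id=f"{group}{k + 1:02d}",
                                 group=group, gain_scale=scale))
    return recs


# ---------------------------------------------------------------- axon tables

@dataclass(frozen=True)
class AxonPopulationSpec:
    """Axon diameter and g-ratio generating law.

    Inner diameters are log-normal (nm); g is the baseline plus, in treated
    animals only and only below ``threshold_nm``, the planted shift, plus
    Gaussian noise, clipped into (0, 1).  Outer diameter = inner / g.
    """

    n_axons: int = 500
    diameter_log_mu: float = math.log(450.0)
    diameter_log_sigma: float = 0.45
    gratio_baseline: float = 0.8
    gratio_shift_below_threshold: float = -0.05
    threshold_nm: float = 400.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_axons < 1:
            raise ValueError("n_axons must be positive")
        if self.threshold_nm <= 0:
            raise ValueError("threshold_nm must be positive")
        for value in (self.gratio_baseline,
                      self.gratio_baseline + self.gratio_shift_below_threshold):
            if not 0.05 < value < 0.98:
                raise ValueError("g-ratio parameters imply g outside (0, 1) "
                                 "for the bulk of the population")


def simulate_axons(spec: AxonPopulationSpec, group: str,
                   treated: bool = False) -> pd.DataFrame:
    """Generate an axon table (group, inner_nm, outer_nm, g) for one group."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    inner = rng.lognormal(spec.diameter_log_mu, spec.diameter_log_sigma,
                          spec.n_axons)
    g = np.full(spec.n_axons, spec.gratio_baseline)
    if treated:
        g[inner < spec.threshold_nm] += spec.gratio_shift_below_threshold
    g = np.clip(g + rng.normal(0.0, spec.noise_sd, spec.n_axons), 0.05, 0.98)
    return pd.DataFrame({"group": group, "inner_nm": inner,
                         "outer_nm": inner / g, "g": g})


# --------------------------------------------------------------- fiber images

def simulate_fiber_image(n_curves: int = 20, curve_length_px: int = 100,
                         image_size: tuple[int, int] = (256, 256),
                         seed: int = 0, turn_sd: float = 0.15
                         ) -> tuple[np.ndarray, float, int]:
    """Rasterize random smooth curves into a binary image.

    Each curve is a unit-step random walk with smoothly drifting heading,
    reflected at the borders; ``curve_length_px`` pixels means
    ``curve_length_px - 1`` unit steps, so a straight 100-pixel segment has
    ground-truth length 99 (inter-pixel step convention).

    Returns (binary image, analytic polyline length in px, planted crossing
    count between distinct curves).
    """
    h, w = image_size
    if min(h, w) < 16:
        raise ValueError("image too small")
    if n_curves < 1 or curve_length_px < 2:
        raise ValueError("need at least one curve of at least 2 pixels")
    if n_curves * curve_length_px > 0.5 * h * w:
        raise ValueError("image too small for the requested curves")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    owner = np.full((h, w), -1, dtype=np.int64)
    multi = np.zeros((h, w), dtype=bool)
    margin = 2.0
    total_length = 0.0
    for c in range(n_curves):
        r = rng.uniform(margin, h - 1 - margin)
        col = rng.uniform(margin, w - 1 - margin)
        theta = rng.uniform(0, 2 * np.pi)
        pts = [(r, col)]
        for _ in range(curve_length_px - 1):
            theta += rng.normal(0.0, turn_sd)
            r2 = r + math.sin(theta)
            c2 = col + math.cos(theta)
            if not margin <= r2 <= h - 1 - margin:
                theta = -theta
                r2 = r + math.sin(theta)
            if not margin <= c2 <= w - 1 - margin:
                theta = math.pi - theta
                c2 = col + math.cos(theta)
            r, col = (min(max(r2, 0.0), h - 1.0), min(max(c2, 0.0), w - 1.0))
            pts.append((r, col))
        total_length += sum(
            math.hypot(b[0] - a[0], b[1] - a[1]) for a, b in zip(pts, pts[1:]))
        for pr, pc in pts:
            ir, ic = int(round(pr)), int(round(pc))
            if owner[ir, ic] not in (-1, c):
                multi[ir, ic] = True
            owner[ir, ic] = c
    image = owner >= 0
    from scipy import ndimage
    _, n_crossings = ndimage.label(multi, structure=np.ones((3, 3)))
    return image, float(total_length), int(n_crossings)


# ------------------------------------------------------------------- writers

def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Write a cohort as delimited text: one time-series file per animal,
    a group-label table, the behavior table and the ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for aid, ts in cohort.timeseries.items():
        pd.DataFrame(ts, columns=cohort.roi_names).to_csv(
            outdir / f"timeseries_{aid}.csv", index=False)
    pd.DataFrame({"animal_id": list(cohort.groups),
                  "group": list(cohort.groups.values())}).to_csv(
        outdir / "groups.csv", index=False)
    cohort.behavior.to_csv(outdir / "behavior.csv", index=False)
    (outdir / "truth.json").write_text(json.dumps(cohort.truth, indent=2))
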