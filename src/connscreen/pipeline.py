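"""End-to-end orchestration: FC -> screen -> NMI -> behavior -> companions.

A :class:`PipelineConfig` names the on-disk inputs for each stage; stages
with inputs present run in dependency order and write delimited-text
outputs plus a JSON provenance sidecar (config hash, seed, version).
Partial configs run partial pipelines; a failed stage aborts its dependents
but the report still lists what completed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import load_behavior_table, screen_behavior_table
from .emg import SignalRecording, group_band_compare
from .fc import FCMatrix, fisher_z, group_mean_fc, load_timeseries, pearson_fc
from .fibers import binarize, node_degree_density, skeleton_metrics
from .myelin import GRatioModel, load_axon_table
from .screening import ConnectivityScreen, ScreenConfig, ScreenResults

__all__ = ["PipelineConfig", "RunReport", "run_pipeline",
           "export_chord_edgelist", "load_fc_inputs"]


@dataclass
class PipelineConfig:
    """Paths and knobs for a pipeline run; unset paths skip their stage."""

    fc_dir: str | None = None          # timeseries_<animal>.csv + groups.csv
    behavior_path: str | None = None   # long table: animal_id, metric, value
    emg_dir: str | None = None         # emg_<animal>.csv + emg_groups.csv
    axon_path: str | None = None       # group, inner_nm/outer_nm or areas
    fiber_paths: list[str] = field(default_factory=list)
    out_dir: str = "connscreen_out"
    treated_group: str = "A"
    control_group: str = "B"
    alpha: float = 0.01
    correction: str = "bh_fdr"
    d_threshold: float = 0.8
    test_variant: str = "student"
    nmi_fraction: float = 0.10
    fiber_pixel_size_um: float = 1.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)

    def screen_config(self) -> ScreenConfig:
        return ScreenConfig(alpha=self.alpha, correction=self.correction,
                            d_threshold=self.d_threshold,
                            test_variant=self.test_variant)

    def hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    """Per-stage outputs and provenance of one pipeline run."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    completed: list[str] = field(default_factory=list)
    errors: dict[str, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    screen: ScreenResults | None = None

    def summary(self) -> str:
        lines = [f"pipeline run (config {self.provenance.get('config_hash', '?')})",
                 f"completed stages: {', '.join(self.completed) or 'none'}"]
        for stage, err in self.errors.items():
            lines.append(f"FAILED {stage}: {err}")
        if self.screen is not None:
            lines.append(self.screen.summary())
        return "\n".join(lines)


def load_fc_inputs(fc_dir) -> tuple[dict[str, FCMatrix], dict[str, str]]:
    """Read per-animal time series and group labels from a cohort directory."""
    fc_dir = Path(fc_dir)
    groups = pd.read_csv(fc_dir / "groups.csv").set_index("animal_id")["group"]
    matrices = {}
    for path in sorted(fc_dir.glob("timeseries_*.csv")):
        aid = path.stem.removeprefix("timeseries_")
        matrices[aid] = pearson_fc(load_timeseries(path), tag=aid)
    missing = set(matrices) - set(groups.index.astype(str))
    if missing:
        raise ValueError(f"animals without group labels: {sorted(missing)}")
    return matrices, {aid: str(groups[aid]) for aid in matrices}


def export_chord_edgelist(screen: ScreenResults, path,
                          kind: str = "intersection") -> pd.DataFrame:
    """Write the chord-diagram edge list for the screened set."""
    table = screen.chord_edgelist(kind)
    table.to_csv(path, index=False)
    return table


def run_pipeline(config: PipelineConfig) -> RunReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    report.provenance = {"config_hash": config.hash(), "seed": config.seed,
                         "version": __version__, "config": asdict(config)}

    fc_ok = False
    if config.fc_dir:
        try:
            matrices, groups = load_fc_inputs(config.fc_dir)
            by_group: dict[str, list[FCMatrix]] = {}
            for aid, m in matrices.items():
                by_group.setdefault(groups[aid], []).append(m)
            for label, mats in by_group.items():
                group_mean_fc(mats, tag=label).to_frame().to_csv(
                    out / f"group_mean_fc_{label}.csv")
            report.completed.append("fc")
            fc_ok = True
        except Exception as exc:  # noqa: BLE001 - reported, dependents skipped
            report.errors["fc"] = str(exc)

    if fc_ok:
        try:
            model = ConnectivityScreen(by_group[config.treated_group],
                                       by_group[config.control_group])
            screen = model.fit(config.screen_config())
            report.screen = screen
            screen.edges.to_csv(out / "edge_results.csv", index=False)
            export_chord_edgelist(screen, out / "chord_edges.csv")
            report.tables["edges"] = screen.edges
            report.completed.append("screen")

            nmi = screen.nmi(fraction=config.nmi_fraction)
            nmi.to_frame().to_csv(out / "nmi.csv", index=False)
            report.tables["nmi"] = nmi.to_frame()
            report.completed.append("nmi")
        except Exception as exc:  # noqa: BLE001
            report.errors["screen"] = str(exc)

    if config.behavior_path and report.screen is not None:
        try:
            behavior = load_behavior_table(config.behavior_path)
            edges = report.screen.selected_edges("intersection")
            if not edges:
                edges = report.screen.selected_edges("effect")
            z_frame = _edge_z_frame(matrices, edges)
            table = screen_behavior_table(z_frame, behavior, edges)
            table.to_csv(out / "behavior_correlations.csv", index=False)
            report.tables["behavior"] = table
            report.completed.append("behavior")
        except Exception as exc:  # noqa: BLE001
            report.errors["behavior"] = str(exc)

    if config.emg_dir:
        try:
            table = _emg_stage(config.emg_dir)
            table.to_csv(out / "emg_band_compare.csv", index=False)
            report.tables["emg"] = table
            report.completed.append("emg")
        except Exception as exc:  # noqa: BLE001
            report.errors["emg"] = str(exc)

    if config.axon_path:
        try:
            axons = load_axon_table(config.axon_path)
            results = GRatioModel(axons, treated=config.treated_group,
                                  control=config.control_group).fit()
            results.strata.to_csv(out / "gratio_strata.csv", index=False)
            report.tables["gratio"] = results.strata
            report.completed.append("myelin")
        except Exception as exc:  # noqa: BLE001
            report.errors["myelin"] = str(exc)

    if config.fiber_paths:
        try:
            table = _fiber_stage(config.fiber_paths, config.fiber_pixel_size_um)
            table.to_csv(out / "fiber_metrics.csv", index=False)
            report.tables["fibers"] = table
            report.completed.append("fibers")
        except Exception as exc:  # noqa: BLE001
            report.errors["fibers"] = str(exc)

    (out / "provenance.json").write_text(json.dumps(report.provenance, indent=2,
                                                    default=str))
    (out / "run_report.txt").write_text(report.summary() + "\n")
    return report


def _edge_z_frame(matrices: dict[str, FCMatrix], edges) -> pd.DataFrame:
    rows = {}
    for aid, m in matrices.items():
        z = fisher_z(m)
        idx = {n: k for k, n in enumerate(z.roi_names)}
        rows[aid] = [z.values[idx[i], idx[j]] for i, j in edges]
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(edges))


def _emg_stage(emg_dir) -> pd.DataFrame:
    emg_dir = Path(emg_dir)
    groups = pd.read_csv(emg_dir / "emg_groups.csv").set_index("animal_id")
    recs: dict[str, list[SignalRecording]] = {}
    for path in sorted(emg_dir.glob("emg_*.csv")):
        aid = path.stem.removeprefix("emg_")
        if aid == "groups":
            continue
        df = pd.read_csv(path)
        rec = SignalRecording(samples=df["value"].to_numpy(),
                              fs=float(groups.loc[aid, "fs"]),
                              labels=df["state"].to_numpy() == "wake",
                              animal_id=aid, group=str(groups.loc[aid, "group"]))
        recs.setdefault(rec.group, []).append(rec)
    labels = sorted(recs)
    if len(labels) != 2:
        raise ValueError("EMG stage needs exactly two groups")
    return group_band_compare(recs[labels[0]], recs[labels[1]])


def _fiber_stage(paths, pixel_size_um: float) -> pd.DataFrame:
    import imageio.v3 as iio

    rows = []
    for path in paths:
        img = np.asarray(iio.imread(path))
        if img.ndim == 3:
            img = img[..., 0]
        binary = binarize(img)
        length, branches, graph = skeleton_metrics(binary, pixel_size_um)
        hist = node_degree_density(graph)
        rows.append({"image": str(path), "total_length_um": length,
                     "n_branch_points": branches,
                     "degree_density": json.dumps(hist)})
    return pd.DataFrame(rows)
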