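"""End-to-end orchestration: simulate a cohort, compute per-subject
z-maps, form the group contrast, and write report tables + provenance.

Configuration lives in a single YAML file (CLI flags override it). Two
runs with identical configuration and inputs produce identical numerical
outputs; provenance records carry a timestamp and are metadata, not data.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as scio
from .connectivity import subject_zmap
from .group import (
    difference_map,
    group_mean_map,
    render_report,
    roi_summary,
    threshold_clusters,
)
from .synthetic import SimulationConfig, default_roi_definition, generate_cohort
from .types import (
    ConfigError,
    DofPolicy,
    FilterConfig,
    GroupContrastConfig,
    QCLog,
    ROIDefinition,
)


@dataclass
class RunConfig:
    """Resolved configuration for a full pipeline run."""

    out_dir: Path
    simulation: SimulationConfig
    n_per_group: int = 3
    seed_center: tuple[int, int, int] = (12, 12, 8)
    harmonics_m: int = 2
    lowpass_hz: float = 0.08
    hamming_enabled: bool = True
    dof_policy: DofPolicy = field(default_factory=DofPolicy)
    sd_mode: str = "population"
    contrast: GroupContrastConfig = field(default_factory=GroupContrastConfig)
    z_floor: float = 2.3
    rng_seed: int = 0

    def filter_config(self) -> FilterConfig:
        return FilterConfig(lowpass_hz=self.lowpass_hz,
                            tr_s=self.simulation.tr_s,
                            hamming_enabled=self.hamming_enabled)


def load_run_config(path: str | Path, overrides: dict | None = None) -> RunConfig:
    """Parse a YAML run configuration; unknown keys raise ConfigError."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})
    known = {"out_dir", "simulate", "n_per_group", "seed_center", "harmonics",
             "lowpass_hz", "hamming", "dof", "sd_mode", "contrast", "z_floor",
             "rng_seed"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
    if "out_dir" not in raw:
        raise ConfigError("config must set out_dir")

    sim_kwargs = dict(raw.get("simulate") or {})
    for key in ("grid_dims", "voxel_size_mm"):
        if key in sim_kwargs:
            sim_kwargs[key] = tuple(sim_kwargs[key])
    if "node_centers" in sim_kwargs:
        sim_kwargs["node_centers"] = tuple(tuple(c) for c in sim_kwargs["node_centers"])
    try:
        sim = SimulationConfig(**sim_kwargs)
    except TypeError as exc:
        raise ConfigError(f"invalid simulate section: {exc}") from exc

    dof_raw = raw.get("dof", "nominal")
    if dof_raw == "nominal":
        dof = DofPolicy()
    else:
        dof = DofPolicy(mode="fixed", fixed_dof=int(dof_raw))

    contrast = GroupContrastConfig(**(raw.get("contrast") or {}))
    return RunConfig(
        out_dir=Path(raw["out_dir"]),
        simulation=sim,
        n_per_group=int(raw.get("n_per_group", 3)),
        seed_center=tuple(raw.get("seed_center", (12, 12, 8))),
        harmonics_m=int(raw.get("harmonics", 2)),
        lowpass_hz=float(raw.get("lowpass_hz", 0.08)),
        hamming_enabled=bool(raw.get("hamming", True)),
        dof_policy=dof,
        sd_mode=str(raw.get("sd_mode", "population")),
        contrast=contrast,
        z_floor=float(raw.get("z_floor", 2.3)),
        rng_seed=int(raw.get("rng_seed", 0)),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_provenance(out_dir: Path, stage: str, params: dict,
                     inputs: list[Path], outputs: list[Path]) -> Path:
    """Record tool version, parameters, and file digests for one stage."""
    record = {
        "tool": "seedconn",
        "version": __version__,
        "stage": stage,
        "parameters": params,
        "inputs": {p.name: _sha256(p) for p in inputs if p.exists()},
        "outputs": {p.name: _sha256(p) for p in outputs if p.exists()},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path = out_dir / f"provenance_{stage}.json"
    path.write_text(json.dumps(record, indent=2, sort_keys=True))
    return path


def run_simulate(cfg: RunConfig) -> pd.DataFrame:
    """Generate the synthetic cohort and write manifest + provenance."""
    data_dir = cfg.out_dir / "data"
    manifest = generate_cohort(cfg.simulation, cfg.n_per_group,
                               cfg.rng_seed, data_dir)
    write_provenance(
        cfg.out_dir, "simulate",
        {"n_per_group": cfg.n_per_group, "rng_seed": cfg.rng_seed,
         "grid_dims": list(cfg.simulation.grid_dims),
         "amp_by_group": cfg.simulation.amp_by_group},
        inputs=[],
        outputs=[data_dir / "manifest.tsv", data_dir / "mask.nii.gz"],
    )
    return manifest


def run_full(cfg: RunConfig, manifest: pd.DataFrame | None = None,
             rois: ROIDefinition | None = None) -> dict[str, Path]:
    """Simulate (unless a manifest is given), map every subject, contrast
    the groups, and write all declared outputs under ``cfg.out_dir``.

    The difference map is the first group label (sorted) minus the
    second. Returns a name -> path dict of the written outputs.
    """
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    if manifest is None:
        manifest = run_simulate(cfg)
    data_dir = Path(manifest["image_path"].iloc[0]).parent
    mask = scio.read_mask(data_dir / "mask.nii.gz")

    if rois is None:
        rois = ROIDefinition(
            label_map=default_roi_definition(cfg.simulation),
            names={i + 1: f"node_{i}" for i in range(len(cfg.simulation.node_centers))},
        )

    filt = cfg.filter_config()
    zmap_dir = cfg.out_dir / "zmaps"
    zmap_dir.mkdir(exist_ok=True)
    outputs: dict[str, Path] = {}
    zmaps_by_group: dict[str, list] = {}
    roi_frames = []
    qc = QCLog()
    for row in manifest.itertuples(index=False):
        img = scio.read_image_4d(row.image_path)
        physio = scio.read_physio(row.physio_path)
        zmap = subject_zmap(img, physio, cfg.seed_center, mask, cfg=filt,
                            dof_policy=cfg.dof_policy,
                            harmonics_m=cfg.harmonics_m,
                            sd_mode=cfg.sd_mode, qc=qc)
        zpath = zmap_dir / f"{row.subject_id}_z.nii.gz"
        scio.write_stat_map(zmap, zpath, voxel_size_mm=img.voxel_size_mm,
                            extra={"subject_id": row.subject_id,
                                   "seed_center": list(cfg.seed_center),
                                   "dof": cfg.dof_policy.dof(img.n_timepoints),
                                   "sd_mode": cfg.sd_mode,
                                   "lowpass_hz": filt.lowpass_hz,
                                   "harmonics_m": cfg.harmonics_m,
                                   "hamming": filt.hamming_enabled})
        outputs[f"zmap_{row.subject_id}"] = zpath
        zmaps_by_group.setdefault(row.group, []).append(zmap)
        roi_frames.append(roi_summary(zmap, rois, z_floor=cfg.z_floor,
                                      subject_id=row.subject_id, group=row.group))

    groups = sorted(zmaps_by_group)
    if len(groups) != 2:
        raise ConfigError(f"group contrast requires 2 groups, got {groups}")
    g_a, g_b = groups
    mean_a = group_mean_map(zmaps_by_group[g_a], mask)
    mean_b = group_mean_map(zmaps_by_group[g_b], mask)
    for name, m in ((g_a, mean_a), (g_b, mean_b)):
        path = cfg.out_dir / f"group_mean_{name}.nii.gz"
        scio.write_stat_map(m, path, voxel_size_mm=cfg.simulation.voxel_size_mm,
                            extra={"group": name})
        outputs[f"group_mean_{name}"] = path

    diff = difference_map(mean_a, mean_b, cfg.contrast,
                          n_a=len(zmaps_by_group[g_a]),
                          n_b=len(zmaps_by_group[g_b]))
    diff_path = cfg.out_dir / "group_diff.nii.gz"
    scio.write_stat_map(diff, diff_path,
                        voxel_size_mm=cfg.simulation.voxel_size_mm,
                        extra={"contrast": f"{g_a} - {g_b}",
                               "diff_mode": cfg.contrast.diff_mode})
    outputs["group_diff"] = diff_path

    thresholded, clusters = threshold_clusters(diff, cfg.contrast, mask)
    thr_path = cfg.out_dir / "group_diff_thresholded.nii.gz"
    scio.write_stat_map(thresholded, thr_path,
                        voxel_size_mm=cfg.simulation.voxel_size_mm,
                        extra={"alpha": cfg.contrast.alpha,
                               "two_sided": cfg.contrast.two_sided,
                               "min_cluster_vox": cfg.contrast.min_cluster_vox,
                               "connectivity": cfg.contrast.connectivity})
    outputs["group_diff_thresholded"] = thr_path

    roi_rows = pd.concat(roi_frames, ignore_index=True)
    report_dir = cfg.out_dir / "report"
    report_paths = render_report(clusters, roi_rows, report_dir)
    outputs.update({f"report_{k}": v for k, v in report_paths.items()})

    write_provenance(
        cfg.out_dir, "full",
        {"seed_center": list(cfg.seed_center), "lowpass_hz": filt.lowpass_hz,
         "harmonics_m": cfg.harmonics_m, "hamming": filt.hamming_enabled,
         "sd_mode": cfg.sd_mode, "z_floor": cfg.z_floor,
         "alpha": cfg.contrast.alpha, "two_sided": cfg.contrast.two_sided,
         "min_cluster_vox": cfg.contrast.min_cluster_vox,
         "connectivity": cfg.contrast.connectivity,
         "diff_mode": cfg.contrast.diff_mode,
         "contrast": f"{g_a} - {g_b}",
         "qc_zero_variance_voxels": qc.zero_variance_voxels,
         "qc_clipped_correlations": qc.clipped_correlations},
        inputs=[Path(p) for p in manifest["image_path"]],
        outputs=list(outputs.values()),
    )
    return outputs
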