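"""Group-level maps, cluster-extent thresholding, and summary tables.

Subject z-maps are averaged per group; the group difference map (group A
minus group B) is thresholded at a single-voxel p (default 0.05,
two-sided) with a cluster-extent requirement of more than 30 connected
voxels. ROI summaries report, per subject and region, the mean, sample
standard deviation, and count of suprathreshold voxels; group rows
summarize the per-subject means with the sample (n-1) SD convention and
half-up rounding to two decimals for report output.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .types import (
    BrainMask,
    GroupContrastConfig,
    ROIDefinition,
    StatMap,
    ValidationError,
    check_same_grid,
)

_STRUCTURES = {
    "faces": ndimage.generate_binary_structure(3, 1),
    "faces+edges": ndimage.generate_binary_structure(3, 2),
    "faces+edges+corners": ndimage.generate_binary_structure(3, 3),
}

CLUSTER_COLUMNS = ["cluster_id", "size_vox", "peak_value",
                   "peak_x", "peak_y", "peak_z",
                   "centroid_x", "centroid_y", "centroid_z", "sign"]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round-half-up (0.005 -> 0.01), the convention of printed tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def group_mean_map(zmaps: list[StatMap], mask: BrainMask) -> StatMap:
    """Voxelwise arithmetic mean of subject z-maps, in-mask only."""
    if not zmaps:
        raise ValidationError("group_mean_map requires at least one map")
    for m in zmaps:
        check_same_grid(m.shape, mask.shape)
    stack = np.stack([m.data for m in zmaps], axis=0)
    out = np.full(mask.shape, np.nan)
    out[mask.data] = stack[:, mask.data].mean(axis=0)
    return StatMap(data=out, kind="mean_z", mask_applied=True)


def difference_map(mean_a: StatMap, mean_b: StatMap, cfg: GroupContrastConfig,
                   n_a: int, n_b: int) -> StatMap:
    """Group difference map, A minus B.

    ``naive_diff`` is the raw voxelwise difference of the group means.
    ``standardized_diff`` divides by sqrt(1/n_a + 1/n_b), the null SD of
    a difference of means of unit-variance maps, giving a z-statistic.
    """
    check_same_grid(mean_a.shape, mean_b.shape)
    diff = mean_a.data - mean_b.data
    if cfg.diff_mode == "standardized_diff":
        if n_a < 1 or n_b < 1:
            raise ValidationError("group sizes must be >= 1")
        diff = diff / np.sqrt(1.0 / n_a + 1.0 / n_b)
    return StatMap(data=diff, kind="diff_z",
                   mask_applied=mean_a.mask_applied or mean_b.mask_applied)


def critical_z(cfg: GroupContrastConfig) -> float:
    """Single-voxel threshold implied by alpha under the normal reference."""
    if cfg.two_sided:
        return float(stats.norm.ppf(1.0 - cfg.alpha / 2.0))
    return float(stats.norm.ppf(1.0 - cfg.alpha))


def threshold_clusters(
    diff: StatMap, cfg: GroupContrastConfig, mask: BrainMask
) -> tuple[StatMap, pd.DataFrame]:
    """Voxel threshold + cluster-extent filter on a difference map.

    Voxels pass when |value| >= z_crit (two-sided) or value >= z_crit
    (one-sided). Connected components are found separately for positive
    and negative suprathreshold voxels under the configured neighbourhood,
    and components smaller than ``min_cluster_vox`` are zeroed. Returns
    the thresholded map and a cluster table sorted by descending size.
    """
    check_same_grid(diff.shape, mask.shape)
    z_crit = critical_z(cfg)
    vals = np.where(mask.data, diff.data, 0.0)
    vals = np.nan_to_num(vals, nan=0.0)
    structure = _STRUCTURES[cfg.connectivity]

    passing_signs = [("+", vals >= z_crit)]
    if cfg.two_sided:
        passing_signs.append(("-", vals <= -z_crit))

    kept = np.zeros(diff.shape, dtype=bool)
    rows = []
    cluster_id = 0
    for sign, passing in passing_signs:
        labels, n = ndimage.label(passing, structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(labels.ravel())[1:]
        for lab in range(1, n + 1):
            size = int(sizes[lab - 1])
            if size < cfg.min_cluster_vox:
                continue
            cluster_id += 1
            sel = labels == lab
            kept |= sel
            coords = np.argwhere(sel)
            cluster_vals = vals[sel]
            peak_i = int(np.argmax(np.abs(cluster_vals)))
            peak_voxel = coords[peak_i]
            centroid = coords.mean(axis=0)
            rows.append({
                "cluster_id": cluster_id,
                "size_vox": size,
                "peak_value": float(cluster_vals[peak_i]),
                "peak_x": int(peak_voxel[0]), "peak_y": int(peak_voxel[1]),
                "peak_z": int(peak_voxel[2]),
                "centroid_x": float(centroid[0]), "centroid_y": float(centroid[1]),
                "centroid_z": float(centroid[2]),
                "sign": sign,
            })

    table = pd.DataFrame(rows, columns=CLUSTER_COLUMNS)
    if len(table):
        table = (table.sort_values(["size_vox", "cluster_id"],
                                   ascending=[False, True])
                 .reset_index(drop=True))
        table["cluster_id"] = np.arange(1, len(table) + 1)
    out = np.where(kept, diff.data, 0.0)
    thresholded = StatMap(data=out, kind="diff_z", mask_applied=diff.mask_applied)
    return thresholded, table


def roi_summary(zmap: StatMap, rois: ROIDefinition, z_floor: float = 2.3,
                subject_id: str = "", group: str = "") -> pd.DataFrame:
    """Per-region mean / sample SD / voxel count over suprathreshold voxels.

    A voxel qualifies when its label matches the region and z >= z_floor.
    Regions with no qualifying voxels report count 0 and missing mean/SD;
    a single qualifying voxel has an undefined sample SD (missing).
    """
    check_same_grid(zmap.shape, rois.label_map.shape)
    rows = []
    for label in sorted(rois.names):
        region = rois.names[label]
        sel = (rois.label_map == label) & np.isfinite(zmap.data) & (zmap.data >= z_floor)
        vals = zmap.data[sel]
        n = int(vals.size)
        rows.append({
            "subject_id": subject_id,
            "group": group,
            "region": region,
            "mean_z": float(vals.mean()) if n >= 1 else np.nan,
            "sd_z": float(vals.std(ddof=1)) if n >= 2 else np.nan,
            "n_voxels": n,
        })
    return pd.DataFrame(rows)


@dataclass
class GroupSummary:
    """Mean and sample SD of one scalar across a group's subjects."""

    group: str
    values: np.ndarray
    mean: float
    sd: float | None
    n: int

    def rounded(self, ndigits: int = 2) -> tuple[float, float | None]:
        sd = None if self.sd is None else round_half_up(self.sd, ndigits)
        return round_half_up(self.mean, ndigits), sd


def group_summary(values, group: str = "") -> GroupSummary:
    """Arithmetic mean and sample (n-1) standard deviation of per-subject
    scalars; SD is undefined (None) for n = 1."""
    vals = np.asarray(list(values), dtype=np.float64)
    if vals.size == 0:
        raise ValidationError("group_summary requires at least one value")
    sd = float(vals.std(ddof=1)) if vals.size >= 2 else None
    return GroupSummary(group=group, values=vals, mean=float(vals.mean()),
                        sd=sd, n=int(vals.size))


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return ""
    return f"{round_half_up(float(x), 2):.2f}"


def render_report(cluster_table: pd.DataFrame, roi_rows: pd.DataFrame,
                  out_dir: str | Path) -> dict[str, Path]:
    """Write the cluster table and ROI/group tables as deterministic TSVs.

    ``roi_table.tsv`` mirrors the usual case-series layout: one row per
    subject with M/SD/V triplets per region, followed by group Mean and
    SD rows (sample SD over the subjects' means, half-up to 2 decimals).
    ``group_summary.tsv`` holds the per-(group, region) summary in long
    form; ``clusters.tsv`` lists surviving clusters.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    clusters_path = out / "clusters.tsv"
    cluster_table.to_csv(clusters_path, sep="\t", index=False)
    paths["clusters"] = clusters_path

    regions = list(dict.fromkeys(roi_rows["region"])) if len(roi_rows) else []
    header = ["participant"]
    for region in regions:
        header += [f"{region}|M", f"{region}|SD", f"{region}|V"]

    lines = ["\t".join(header)]
    groups = list(dict.fromkeys(roi_rows["group"])) if len(roi_rows) else []
    long_rows = []
    for grp in groups:
        sub_df = roi_rows[roi_rows["group"] == grp]
        subjects = list(dict.fromkeys(sub_df["subject_id"]))
        for sid in subjects:
            row = [sid]
            for region in regions:
                rec = sub_df[(sub_df["subject_id"] == sid)
                             & (sub_df["region"] == region)]
                if len(rec):
                    rec = rec.iloc[0]
                    row += [_fmt(rec["mean_z"]), _fmt(rec["sd_z"]),
                            str(int(rec["n_voxels"]))]
                else:
                    row += ["", "", ""]
            lines.append("\t".join(row))
        mean_row, sd_row = [f"{grp} Mean"], [f"{grp} SD"]
        for region in regions:
            means = sub_df[sub_df["region"] == region]["mean_z"].dropna().to_numpy()
            if means.size:
                gs = group_summary(means, group=grp)
                m, sd = gs.rounded(2)
                mean_row += [f"{m:.2f}", "", ""]
                sd_row += ["" if sd is None else f"{sd:.2f}", "", ""]
                long_rows.append({"group": grp, "region": region,
                                  "group_mean": m,
                                  "group_sd": sd, "n_subjects": gs.n})
            else:
                mean_row += ["", "", ""]
                sd_row += ["", "", ""]
        lines.append("\t".join(mean_row))
        lines.append("\t".join(sd_row))

    roi_path = out / "roi_table.tsv"
    roi_path.write_text("\n".join(lines) + "\n")
    paths["roi_table"] = roi_path

    summary_path = out / "group_summary.tsv"
    pd.DataFrame(long_rows, columns=["group", "region", "group_mean",
                                     "group_sd", "n_subjects"]).to_csv(
        summary_path, sep="\t", index=False)
    paths["group_summary"] = summary_path
    return paths
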