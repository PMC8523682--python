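"""Reading and writing the volumetric and tabular formats the pipeline uses.

NIfTI-1 carries images, masks, ROI label maps and stat maps; manifests are
TSV; stat-map kind and provenance travel in a JSON sidecar next to the
volume (the NIfTI header has no standard slot for them). All images are
reoriented to canonical (RAS) axes on load; voxel coordinates elsewhere in
the package always refer to this canonical grid.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .types import (
    BrainMask,
    DimensionalityError,
    Image4D,
    PhysioTrace,
    ROIDefinition,
    SchemaError,
    StatMap,
    ValidationError,
)

MANIFEST_COLUMNS = ["subject_id", "group", "image_path", "physio_path", "rng_seed"]


def _affine(voxel_size_mm: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def _sidecar_path(path: str | Path) -> Path:
    p = Path(path)
    name = p.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return p.with_name(name[: -len(suffix)] + ".json")
    return p.with_suffix(".json")


def read_image_4d(path: str | Path, tr_s: float | None = None) -> Image4D:
    """Load a 4D NIfTI series, reoriented to canonical axes.

    TR is taken from the header (pixdim[4]) unless overridden with
    ``tr_s``. A 3D file raises :class:`DimensionalityError`.
    """
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise DimensionalityError(
            f"{path}: expected a 4D image, got {data.ndim} axes"
        )
    zooms = img.header.get_zooms()
    header_tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    tr = float(tr_s) if tr_s is not None else header_tr
    if tr <= 0:
        raise ValidationError(
            f"{path}: TR missing from header; pass tr_s explicitly"
        )
    return Image4D(
        data=np.asarray(data, dtype=np.float64),
        voxel_size_mm=tuple(float(z) for z in zooms[:3]),
        tr_s=tr,
    )


def write_image_4d(img: Image4D, path: str | Path) -> Path:
    """Write a 4D series as NIfTI-1 with TR stored in pixdim[4]."""
    nii = nib.Nifti1Image(img.data.astype(np.float32), _affine(img.voxel_size_mm))
    nii.header.set_zooms(tuple(img.voxel_size_mm) + (img.tr_s,))
    nii.header.set_xyzt_units("mm", "sec")
    nib.save(nii, str(path))
    return Path(path)


def write_stat_map(
    stat: StatMap,
    path: str | Path,
    voxel_size_mm: tuple[float, float, float] = (1.2, 1.2, 1.5),
    extra: dict | None = None,
) -> Path:
    """Write a stat map volume plus a JSON sidecar holding its kind.

    Values are stored as float32; NaN (off-mask) voxels round-trip.
    """
    nii = nib.Nifti1Image(stat.data.astype(np.float32), _affine(voxel_size_mm))
    nib.save(nii, str(path))
    meta = {"kind": stat.kind, "mask_applied": bool(stat.mask_applied)}
    if extra:
        meta.update(extra)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return Path(path)


def read_stat_map(path: str | Path) -> StatMap:
    """Load a stat map and its kind from the JSON sidecar."""
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asarray(np.asanyarray(img.dataobj), dtype=np.float64)
    if data.ndim != 3:
        raise DimensionalityError(f"{path}: stat maps are 3D, got {data.ndim} axes")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ValidationError(f"{path}: missing sidecar {sidecar.name}")
    meta = json.loads(sidecar.read_text())
    return StatMap(data=data, kind=meta["kind"], mask_applied=meta.get("mask_applied", False))


def write_mask(mask: BrainMask, path: str | Path,
               voxel_size_mm: tuple[float, float, float] = (1.2, 1.2, 1.5)) -> Path:
    """Store a mask as an 8-bit volume, nonzero = in brain."""
    nii = nib.Nifti1Image(mask.data.astype(np.uint8), _affine(voxel_size_mm))
    nib.save(nii, str(path))
    return Path(path)


def read_mask(path: str | Path) -> BrainMask:
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise DimensionalityError(f"{path}: masks are 3D, got {data.ndim} axes")
    return BrainMask(data=data != 0)


def write_roi_definition(rois: ROIDefinition, path: str | Path,
                         voxel_size_mm: tuple[float, float, float] = (1.2, 1.2, 1.5)) -> Path:
    nii = nib.Nifti1Image(rois.label_map.astype(np.int16), _affine(voxel_size_mm))
    nib.save(nii, str(path))
    _sidecar_path(path).write_text(
        json.dumps({"names": {str(k): v for k, v in rois.names.items()}},
                   indent=2, sort_keys=True)
    )
    return Path(path)


def read_roi_definition(path: str | Path) -> ROIDefinition:
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise DimensionalityError(f"{path}: ROI label maps are 3D, got {data.ndim} axes")
    sidecar = _sidecar_path(path)
    names: dict[int, str] = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        names = {int(k): v for k, v in meta.get("names", {}).items()}
    else:
        names = {int(l): f"region_{int(l)}" for l in np.unique(data) if l != 0}
    return ROIDefinition(label_map=data, names=names)


def write_physio(trace: PhysioTrace, path: str | Path) -> Path:
    """Two whitespace-delimited columns: cardiac_phase, resp_phase per volume."""
    arr = np.column_stack([trace.cardiac_phase, trace.resp_phase])
    np.savetxt(str(path), arr, fmt="%.10f", header="cardiac_phase resp_phase")
    return Path(path)


def read_physio(path: str | Path) -> PhysioTrace:
    arr = np.loadtxt(str(path))
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise SchemaError(f"{path}: expected two columns (cardiac_phase, resp_phase)")
    return PhysioTrace(cardiac_phase=arr[:, 0], resp_phase=arr[:, 1])


def read_manifest(path: str | Path, require_two_groups: bool = False) -> pd.DataFrame:
    """Read and validate a cohort manifest TSV.

    Requires the columns subject_id/group/image_path/physio_path/rng_seed,
    unique subject IDs, and — when the manifest will feed a group
    contrast — exactly two distinct group labels.
    """
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "group": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: manifest missing column(s) {missing}")
    dupes = df["subject_id"][df["subject_id"].duplicated()].tolist()
    if dupes:
        raise ValidationError(f"{path}: duplicated subject_id(s) {sorted(set(dupes))}")
    if require_two_groups and df["group"].nunique() != 2:
        raise ValidationError(
            f"{path}: group contrast requires exactly 2 groups, "
            f"got {sorted(df['group'].unique())}"
        )
    return df[MANIFEST_COLUMNS].copy()


def write_manifest(df: pd.DataFrame, path: str | Path) -> Path:
    df.to_csv(path, sep="\t", index=False)
    return Path(path)
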