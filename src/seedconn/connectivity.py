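"""Seed definition, reference time series, correlation, Student's t, and
whole-brain z standardization — one z-map per subject.

The connectivity statistic is the zero-lag Pearson correlation between
each voxel's (preprocessed) time series and the reference time series,
the linearly detrended mean of the 9 seed voxels. Each correlation map is
converted to Student's t with t = r * sqrt(dof / (1 - r^2)), and the
whole-brain (in-mask) t distribution is standardized to zero mean and
unit variance, giving the subject's z-map. Standardizing each subject's
map against its own whole-brain distribution accounts for individual
differences in global signal.
"""

from __future__ import annotations

import numpy as np

from .preprocess import linear_detrend, preprocess_subject
from .types import (
    BrainMask,
    DofPolicy,
    FilterConfig,
    Image4D,
    PhysioTrace,
    QCLog,
    ReferenceTimeSeries,
    SeedPlacementError,
    SeedRegion,
    StatMap,
    ValidationError,
    check_same_grid,
)

R_CLIP = 1.0 - 1e-12


def define_seed(center: tuple[int, int, int], mask: BrainMask,
                hemisphere_tag: str = "") -> SeedRegion:
    """The 3x3 single-slice voxel block centred on ``center``.

    Raises a bounds error if the block leaves the grid and a
    seed-placement error (listing the offending voxels) if any block
    voxel is off-mask.
    """
    cx, cy, cz = (int(c) for c in center)
    nx, ny, nz = mask.shape
    if not (1 <= cx <= nx - 2 and 1 <= cy <= ny - 2 and 0 <= cz <= nz - 1):
        raise SeedPlacementError(
            f"3x3 seed block at {center} exits the {mask.shape} grid"
        )
    voxels = np.array(
        [(cx + dx, cy + dy, cz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)],
        dtype=np.intp,
    )
    off_mask = [tuple(int(i) for i in v) for v in voxels
                if not mask.data[v[0], v[1], v[2]]]
    if off_mask:
        raise SeedPlacementError(f"seed block voxels outside the mask: {off_mask}")
    return SeedRegion(voxel_indices=voxels, center=(cx, cy, cz),
                      hemisphere_tag=hemisphere_tag)


def reference_timeseries(img: Image4D, seed: SeedRegion) -> ReferenceTimeSeries:
    """Linearly detrended arithmetic average of the 9 seed-voxel series."""
    idx = seed.voxel_indices
    for v in idx:
        if not all(0 <= v[a] < img.shape[a] for a in range(3)):
            raise ValidationError(f"seed voxel {tuple(v)} outside image grid")
    series = img.data[idx[:, 0], idx[:, 1], idx[:, 2], :]  # (9, T)
    return ReferenceTimeSeries(values=linear_detrend(series.mean(axis=0)),
                               source_seed=seed)


def correlation_map(img: Image4D, ref: ReferenceTimeSeries, mask: BrainMask,
                    qc: QCLog | None = None) -> StatMap:
    """Zero-lag Pearson correlation of every in-mask voxel with the reference.

    Off-mask voxels are NaN. Voxels with zero temporal variance get r = 0
    and are counted in the QC log rather than failing the run.
    """
    check_same_grid(img.shape[:3], mask.shape)
    T = img.n_timepoints
    if T < 4:
        raise ValidationError("correlation_map requires T >= 4")
    r_ts = np.asarray(ref.values, dtype=np.float64)
    if r_ts.shape[0] != T:
        raise ValidationError("reference length must equal image T")
    rc = r_ts - r_ts.mean()
    ref_ss = float(rc @ rc)
    if ref_ss <= 0:
        raise ValidationError("reference time series has zero variance")

    Y = img.data[mask.data]  # (V, T)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    ss = np.einsum("vt,vt->v", Yc, Yc)
    zero_var = ss <= 0
    ss_safe = np.where(zero_var, 1.0, ss)
    r = (Yc @ rc) / np.sqrt(ss_safe * ref_ss)
    r[zero_var] = 0.0
    r = np.clip(r, -1.0, 1.0)
    if qc is not None:
        qc.zero_variance_voxels += int(zero_var.sum())

    out = np.full(mask.shape, np.nan)
    out[mask.data] = r
    return StatMap(data=out, kind="r", mask_applied=True)


def r_to_t(rmap: StatMap, dof: int, qc: QCLog | None = None) -> StatMap:
    """Convert correlations to Student's t: t = r*sqrt(dof/(1-r^2)).

    r is clipped symmetrically to +/-(1 - 1e-12) first so |r| = 1 yields a
    huge but finite t; the conversion is odd and strictly increasing in r.
    """
    if rmap.kind != "r":
        raise ValidationError(f"expected an r map, got kind {rmap.kind!r}")
    if dof < 1:
        raise ValidationError("dof must be >= 1")
    r = rmap.data
    clipped = np.abs(r) > R_CLIP
    if qc is not None:
        qc.clipped_correlations += int(np.nansum(clipped))
    r = np.clip(r, -R_CLIP, R_CLIP)
    t = r * np.sqrt(dof / (1.0 - r**2))
    return StatMap(data=t, kind="t", mask_applied=rmap.mask_applied)


def standardize_whole_brain(tmap: StatMap, mask: BrainMask,
                            sd_mode: str = "population") -> StatMap:
    """Standardize the in-mask distribution to zero mean, unit variance.

    z = (t - mean) / sd over in-mask voxels. The whole-brain map is
    treated as a population, so the default SD divides by N; the sample
    (N-1) convention is selectable and recorded by callers in the
    sidecar. Idempotent, affine-invariant, and rank-preserving.
    """
    if sd_mode not in ("population", "sample"):
        raise ValidationError(f"unknown sd_mode {sd_mode!r}")
    check_same_grid(tmap.shape, mask.shape)
    vals = tmap.data[mask.data]
    if vals.size < 2:
        raise ValidationError("standardization requires >= 2 in-mask voxels")
    mean = vals.mean()
    sd = vals.std(ddof=0 if sd_mode == "population" else 1)
    if sd <= 0 or not np.isfinite(sd):
        raise ValidationError("in-mask variance is zero; cannot standardize")
    z = np.full(tmap.shape, np.nan)
    z[mask.data] = (vals - mean) / sd
    if not tmap.mask_applied:
        off = ~mask.data
        z[off] = (tmap.data[off] - mean) / sd
    return StatMap(data=z, kind="z", mask_applied=tmap.mask_applied)


def subject_zmap(
    img: Image4D,
    physio: PhysioTrace,
    seed_center: tuple[int, int, int],
    mask: BrainMask,
    cfg: FilterConfig | None = None,
    dof_policy: DofPolicy | None = None,
    harmonics_m: int = 2,
    sd_mode: str = "population",
    qc: QCLog | None = None,
) -> StatMap:
    """Full per-subject chain from raw 4D series to standardized z-map.

    Composition: nuisance regression -> in-plane Hamming -> temporal
    low-pass -> seed definition -> reference time series -> correlation
    map -> Student's t -> whole-brain z standardization.
    """
    cfg = cfg or FilterConfig(tr_s=img.tr_s)
    dof_policy = dof_policy or DofPolicy()
    pre = preprocess_subject(img, physio, mask, cfg, harmonics_m=harmonics_m)
    seed = define_seed(seed_center, mask)
    ref = reference_timeseries(pre, seed)
    rmap = correlation_map(pre, ref, mask, qc=qc)
    tmap = r_to_t(rmap, dof_policy.dof(img.n_timepoints), qc=qc)
    return standardize_whole_brain(tmap, mask, sd_mode=sd_mode)
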