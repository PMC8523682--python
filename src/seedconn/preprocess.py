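"""Preprocessing: physiological nuisance regression, in-plane Hamming
spatial filtering, and temporal low-pass filtering below 0.08 Hz.

The stage order is fixed: nuisance regression -> spatial Hamming ->
temporal low-pass. Every operation is linear, and the temporal filter is
an idempotent DFT-bin projection (zero-phase by construction).
"""

from __future__ import annotations

import numpy as np

from .types import (
    BrainMask,
    ConfigError,
    FilterConfig,
    Image4D,
    NuisanceDesign,
    PhysioTrace,
    RankDeficientError,
    ValidationError,
    check_same_grid,
)


def linear_detrend(ts: np.ndarray) -> np.ndarray:
    """Least-squares removal of intercept + linear trend from a series.

    The residual is exactly orthogonal to the constant and to the time
    index 0..T-1.
    """
    ts = np.asarray(ts, dtype=np.float64)
    T = ts.shape[-1]
    if T < 3:
        raise ValidationError("linear_detrend requires T >= 3")
    t = np.arange(T, dtype=np.float64)
    X = np.column_stack([np.ones(T), t])
    coef, *_ = np.linalg.lstsq(X, ts.reshape(-1, T).T, rcond=None)
    resid = ts.reshape(-1, T).T - X @ coef
    return resid.T.reshape(ts.shape)


def build_retroicor_design(physio: PhysioTrace, harmonics_m: int = 2) -> NuisanceDesign:
    """Fourier nuisance basis from cardiac/respiratory phase.

    Columns, in order: intercept; then for k = 1..m the cardiac pair
    sin(k*phi_c), cos(k*phi_c); then for k = 1..m the respiratory pair
    sin(k*phi_r), cos(k*phi_r). Width K = 1 + 4m.
    """
    if harmonics_m < 1:
        raise ConfigError("harmonics_m must be >= 1")
    T = physio.n_timepoints
    cols = [np.ones(T)]
    names = ["intercept"]
    for tag, phase in (("c", physio.cardiac_phase), ("r", physio.resp_phase)):
        for k in range(1, harmonics_m + 1):
            cols.append(np.sin(k * phase))
            names.append(f"sin_{k}phi_{tag}")
            cols.append(np.cos(k * phase))
            names.append(f"cos_{k}phi_{tag}")
    return NuisanceDesign(matrix=np.column_stack(cols), column_names=names,
                          harmonics_m=harmonics_m)


def regress_nuisance(img: Image4D, design: NuisanceDesign,
                     mask: BrainMask) -> Image4D:
    """Replace each in-mask voxel series by its residual against the design.

    Residuals are orthogonal to every design column. A rank-deficient
    design raises :class:`RankDeficientError` naming the dependent
    columns. Off-mask voxels are passed through unchanged.
    """
    X = design.matrix
    T, K = X.shape
    if T != img.n_timepoints:
        raise ValidationError(
            f"design has {T} rows but image has {img.n_timepoints} volumes"
        )
    check_same_grid(img.shape[:3], mask.shape)

    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = max(T, K) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    bad = [design.column_names[i] for i in np.nonzero(diag < tol)[0]]
    if bad:
        raise RankDeficientError(f"design columns linearly dependent: {bad}")

    out = img.data.copy()
    Y = out[mask.data]  # (V, T)
    # residual via the orthonormal basis: Y - (Y Q) Q^T
    out[mask.data] = Y - (Y @ q) @ q.T
    return Image4D(data=out, voxel_size_mm=img.voxel_size_mm, tr_s=img.tr_s,
                   orientation_tag=img.orientation_tag)


def lowpass_temporal(img: Image4D, cfg: FilterConfig) -> Image4D:
    """Hard DFT-domain low-pass: keep bins with |f| <= lowpass_hz (and DC).

    Implemented as a projection onto the retained Fourier bins, so it is
    zero-phase and idempotent; frequencies above the cutoff are removed
    entirely rather than attenuated.
    """
    if cfg.tr_s != img.tr_s:
        cfg = FilterConfig(lowpass_hz=cfg.lowpass_hz, tr_s=img.tr_s,
                           hamming_enabled=cfg.hamming_enabled)
    T = img.n_timepoints
    freqs = np.fft.rfftfreq(T, d=img.tr_s)
    keep = freqs <= cfg.lowpass_hz * (1 + 1e-12)
    spec = np.fft.rfft(img.data, axis=3)
    spec[..., ~keep] = 0.0
    data = np.fft.irfft(spec, n=T, axis=3)
    return Image4D(data=data, voxel_size_mm=img.voxel_size_mm, tr_s=img.tr_s,
                   orientation_tag=img.orientation_tag)


def hamming_window_1d(n: int) -> np.ndarray:
    """Hamming apodization over DC-centred frequency index, unity at DC.

    w(k) = 0.54 + 0.46*cos(pi * |k| / k_max) for the signed DFT frequency
    index k (k_max = n // 2), so w(0) = 1 and w falls to 0.08 at the
    highest spatial frequency.
    """
    k = np.fft.fftfreq(n) * n  # signed integer frequency indices
    k_max = max(np.abs(k).max(), 1.0)
    return 0.54 + 0.46 * np.cos(np.pi * np.abs(k) / k_max)


def hamming_spatial_2d(img: Image4D, mask: BrainMask | None = None) -> Image4D:
    """2D in-plane k-space Hamming apodization, slice by slice.

    Each axial slice's 2D spatial spectrum is multiplied by a separable
    Hamming window (unity at DC), improving functional contrast-to-noise
    at the cost of mild spatial smoothing. The slice mean (DC term) is
    preserved exactly. Filtering acts on the full field of view; the mask
    argument is accepted for interface symmetry but does not restrict the
    k-space operation, which is non-local.
    """
    nx, ny = img.shape[0], img.shape[1]
    if nx < 4 or ny < 4:
        raise ValidationError("in-plane dimensions must be >= 4 for Hamming filtering")
    wx = hamming_window_1d(nx)
    wy = hamming_window_1d(ny)
    window2d = wx[:, None] * wy[None, :]
    spec = np.fft.fft2(img.data, axes=(0, 1))
    spec *= window2d[:, :, None, None]
    data = np.fft.ifft2(spec, axes=(0, 1)).real
    return Image4D(data=data, voxel_size_mm=img.voxel_size_mm, tr_s=img.tr_s,
                   orientation_tag=img.orientation_tag)


def preprocess_subject(
    img: Image4D,
    physio: PhysioTrace,
    mask: BrainMask,
    cfg: FilterConfig,
    harmonics_m: int = 2,
) -> Image4D:
    """Full preprocessing chain in the fixed order.

    nuisance regression (RETROICOR Fourier basis) -> 2D in-plane Hamming
    (if enabled) -> temporal low-pass below ``cfg.lowpass_hz``.
    """
    design = build_retroicor_design(physio, harmonics_m=harmonics_m)
    out = regress_nuisance(img, design, mask)
    if cfg.hamming_enabled:
        out = hamming_spatial_2d(out, mask)
    return lowpass_temporal(out, cfg)
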