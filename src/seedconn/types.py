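"""Core containers and exceptions shared across the pipeline.

Conventions used everywhere in this package:

* Voxel indexing is 0-based with axis order (X, Y, Z) for volumes and
  (X, Y, Z, T) for time series. Seed and ROI coordinates are always
  interpreted on this canonical grid.
* Images loaded from disk are reoriented to canonical (RAS) axes first;
  no registration is performed — inputs are assumed to share a grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STAT_KINDS = ("r", "t", "z", "mean_z", "diff_z")


class PipelineError(Exception):
    """Base class for all seedconn errors."""


class DimensionalityError(PipelineError):
    """An image does not have the expected number of axes."""


class SchemaError(PipelineError):
    """A tabular input is missing required columns."""


class ValidationError(PipelineError):
    """A value violates a documented invariant."""


class ConfigError(PipelineError):
    """An invalid configuration value."""


class GridMismatchError(PipelineError):
    """Two volumes that must share a grid do not."""


class SeedPlacementError(PipelineError):
    """A seed block leaves the grid or touches off-mask voxels."""


class RankDeficientError(PipelineError):
    """A nuisance design matrix has linearly dependent columns."""


@dataclass
class Image4D:
    """A subject's 4D fMRI series: X*Y*Z voxels by T volumes.

    Parameters
    ----------
    data : ndarray, shape (X, Y, Z, T)
        Voxel values; must be finite.
    voxel_size_mm : tuple of 3 floats
        In-plane and through-plane voxel size.
    tr_s : float
        Repetition time in seconds (interval between volumes).
    orientation_tag : str
        Marker that the data are on canonical axes.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.2, 1.2, 1.5)
    tr_s: float = 2.8
    orientation_tag: str = "RAS"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise DimensionalityError(
                f"Image4D requires 4 axes (X, Y, Z, T); got {self.data.ndim}"
            )
        if self.data.shape[3] < 2:
            raise ValidationError("Image4D requires T >= 2 volumes")
        if min(self.data.shape) < 1:
            raise ValidationError("all image dimensions must be >= 1")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("Image4D values must be finite")
        if self.tr_s <= 0:
            raise ConfigError("tr_s must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


@dataclass
class StatMap:
    """A 3D statistic map tagged with its kind.

    ``kind`` is one of r | t | z | mean_z | diff_z. Off-mask voxels are
    NaN when ``mask_applied`` is set. r-kind values must lie in [-1, 1].
    """

    data: np.ndarray
    kind: str
    mask_applied: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"StatMap requires 3 axes; got {self.data.ndim}"
            )
        if self.kind not in STAT_KINDS:
            raise ValidationError(
                f"unknown stat kind {self.kind!r}; expected one of {STAT_KINDS}"
            )
        if self.kind == "r":
            finite = self.data[np.isfinite(self.data)]
            if finite.size and (finite.min() < -1.0 - 1e-12 or finite.max() > 1.0 + 1e-12):
                raise ValidationError("r-kind StatMap values must lie in [-1, 1]")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass
class BrainMask:
    """Boolean X*Y*Z grid marking in-brain voxels (at least one true)."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise DimensionalityError("BrainMask requires 3 axes")
        if not self.data.any():
            raise ValidationError("BrainMask must contain at least one true voxel")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass
class ROIDefinition:
    """Integer label map plus label -> region-name table; 0 is background."""

    label_map: np.ndarray
    names: dict[int, str]

    def __post_init__(self) -> None:
        self.label_map = np.asarray(self.label_map).astype(np.int32)
        if self.label_map.ndim != 3:
            raise DimensionalityError("ROI label map requires 3 axes")
        self.names = {int(k): str(v) for k, v in self.names.items()}
        present = set(np.unique(self.label_map).tolist()) - {0}
        unnamed = present - set(self.names)
        if unnamed:
            raise ValidationError(f"ROI labels without a name: {sorted(unnamed)}")


@dataclass
class PhysioTrace:
    """Cardiac and respiratory phase, one sample per volume, in [0, 2*pi)."""

    cardiac_phase: np.ndarray
    resp_phase: np.ndarray

    def __post_init__(self) -> None:
        self.cardiac_phase = np.mod(np.asarray(self.cardiac_phase, dtype=np.float64), 2 * np.pi)
        self.resp_phase = np.mod(np.asarray(self.resp_phase, dtype=np.float64), 2 * np.pi)
        if self.cardiac_phase.ndim != 1 or self.resp_phase.ndim != 1:
            raise ValidationError("phase traces must be 1-D")
        if self.cardiac_phase.shape != self.resp_phase.shape:
            raise ValidationError("cardiac and respiratory traces must have equal length")

    @property
    def n_timepoints(self) -> int:
        return self.cardiac_phase.shape[0]


@dataclass
class SeedRegion:
    """The 9-voxel seed: a 3x3 single-slice block centred on ``center``."""

    voxel_indices: np.ndarray  # (9, 3) int
    center: tuple[int, int, int]
    hemisphere_tag: str = ""

    def __post_init__(self) -> None:
        self.voxel_indices = np.asarray(self.voxel_indices, dtype=np.intp)
        if self.voxel_indices.shape != (9, 3):
            raise ValidationError("seed must consist of exactly 9 voxel coordinates")
        if len({tuple(v) for v in self.voxel_indices}) != 9:
            raise ValidationError("seed voxels must be distinct")
        if len(set(self.voxel_indices[:, 2].tolist())) != 1:
            raise ValidationError("seed voxels must lie in a single axial plane")


@dataclass
class ReferenceTimeSeries:
    """Linearly detrended mean time course of the 9 seed voxels."""

    values: np.ndarray
    source_seed: SeedRegion | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValidationError("reference time series must be 1-D")


@dataclass
class DofPolicy:
    """Degrees of freedom used for the r -> Student's t conversion.

    ``nominal`` uses T - 2 (the dof of a simple correlation test).
    Temporal filtering reduces the effective dof, so ``fixed`` lets the
    caller supply a value instead.
    """

    mode: str = "nominal"
    fixed_dof: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("nominal", "fixed"):
            raise ConfigError("DofPolicy mode must be 'nominal' or 'fixed'")
        if self.mode == "fixed":
            if self.fixed_dof is None or self.fixed_dof < 1:
                raise ConfigError("fixed DofPolicy requires fixed_dof >= 1")

    def dof(self, n_timepoints: int) -> int:
        if self.mode == "fixed":
            return int(self.fixed_dof)  # type: ignore[arg-type]
        dof = n_timepoints - 2
        if dof < 1:
            raise ConfigError("nominal dof requires T >= 3")
        return dof


@dataclass
class FilterConfig:
    """Temporal low-pass and spatial-filter settings.

    lowpass_hz must sit strictly below the Nyquist frequency 1/(2*TR).
    """

    lowpass_hz: float = 0.08
    tr_s: float = 2.8
    hamming_enabled: bool = True

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise ConfigError("tr_s must be positive")
        nyquist = 1.0 / (2.0 * self.tr_s)
        if not (0.0 < self.lowpass_hz < nyquist):
            raise ConfigError(
                f"lowpass_hz must lie in (0, Nyquist={nyquist:.4f} Hz); got {self.lowpass_hz}"
            )


@dataclass
class NuisanceDesign:
    """T x K regressor matrix: intercept + sin/cos harmonics of each phase.

    The Fourier basis built from physio phases has K = 1 + 4m columns;
    custom designs (e.g. intercept only) may pass ``harmonics_m=None``.
    """

    matrix: np.ndarray
    column_names: list[str]
    harmonics_m: int | None = 2

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValidationError("design matrix must be 2-D (T x K)")
        if self.matrix.shape[1] != len(self.column_names):
            raise ValidationError("column_names length must match design width")
        if self.harmonics_m is not None and self.matrix.shape[1] != 1 + 4 * self.harmonics_m:
            raise ValidationError("design width must equal 1 + 4*harmonics_m")
        if not np.all(np.isfinite(self.matrix)):
            raise ValidationError("design matrix must be finite")


@dataclass
class GroupContrastConfig:
    """Voxel/cluster thresholding and difference-map settings.

    The cluster requirement is 'more than 30 voxels', hence the default
    ``min_cluster_vox`` of 31. ``diff_mode`` selects between the raw
    difference of group mean z-maps (``naive_diff``) and the difference
    scaled by sqrt(1/n_a + 1/n_b) (``standardized_diff``), which is a
    z-statistic under the null for unit-variance subject maps.
    """

    alpha: float = 0.05
    two_sided: bool = True
    min_cluster_vox: int = 31
    connectivity: str = "faces"
    diff_mode: str = "standardized_diff"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError("alpha must lie in (0, 1)")
        if self.min_cluster_vox < 1:
            raise ConfigError("min_cluster_vox must be >= 1")
        if self.connectivity not in ("faces", "faces+edges", "faces+edges+corners"):
            raise ConfigError(f"unknown connectivity {self.connectivity!r}")
        if self.diff_mode not in ("naive_diff", "standardized_diff"):
            raise ConfigError(f"unknown diff_mode {self.diff_mode!r}")


def check_same_grid(*shapes: tuple[int, ...]) -> None:
    """Raise GridMismatchError unless all shapes are equal."""
    first = shapes[0]
    for s in shapes[1:]:
        if tuple(s) != tuple(first):
            raise GridMismatchError(f"grid mismatch: {first} vs {s}")


@dataclass
class QCLog:
    """Per-run quality counters (zero-variance voxels, clipped correlations)."""

    zero_variance_voxels: int = 0
    clipped_correlations: int = 0
    notes: list[str] = field(default_factory=list)
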