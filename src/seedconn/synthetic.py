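"""Synthetic two-group resting-state fMRI cohorts with known ground truth.

The generator emulates the acquisition envelope of a small two-group
resting-state study — 132 volumes at TR = 2.8 s, 3 subjects per group —
on a reduced grid. Each subject's signal model is

    y_v(t) = a * n(t) * [v in a node]
             + physio_amp * (sin(phi_c(t)) + sin(phi_r(t)))
             + drift_slope * t
             + noise_sd * eps_v(t)

where n(t) is a unit-variance latent network source band-limited below
0.08 Hz (so the downstream temporal filter preserves it by construction),
phi_c / phi_r are per-volume cardiac and respiratory phases, and eps is
white Gaussian noise. The theoretical zero-lag correlation of a node
voxel with the source, ignoring the (small) confound terms, is

    true_r = a / sqrt(a^2 + noise_sd^2)

which makes every downstream stage checkable against a closed form. The
two groups differ only in the amplitude a, so any detected group contrast
is attributable to connectivity strength.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as scio
from .types import BrainMask, ConfigError, Image4D, PhysioTrace, StatMap, ValidationError

DEFAULT_NODE_CENTERS = ((12, 12, 8), (5, 5, 8), (18, 17, 8))
DEFAULT_AMPS = {"head-trauma": 0.3, "no-head-trauma": 0.8}


@dataclass
class SimulationConfig:
    """Cohort-generation parameters.

    The defaults encode the study conditions this simulator emulates:
    132 volumes at TR 2.8 s, two groups whose network amplitude differs
    (0.3 for the head-trauma group, 0.8 for the no-head-trauma group,
    against unit noise), a linear scanner drift, and cardiac (~1 Hz) and
    respiratory (~0.3 Hz) phase-locked confounds. The grid is 24x24x16
    voxels — far smaller than a brain — to keep desk-scale runtimes; all
    dimensions are configurable.
    """

    grid_dims: tuple[int, int, int] = (24, 24, 16)
    voxel_size_mm: tuple[float, float, float] = (1.2, 1.2, 1.5)
    n_timepoints: int = 132
    tr_s: float = 2.8
    node_centers: tuple[tuple[int, int, int], ...] = DEFAULT_NODE_CENTERS
    node_radius_vox: int = 2
    amp_by_group: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AMPS))
    noise_sd: float = 1.0
    drift_slope: float = 0.005
    cardiac_hz: float = 1.0
    resp_hz: float = 0.3
    physio_amp: float = 0.1
    phase_jitter_sd: float = 0.05
    source_max_hz: float = 0.08
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timepoints < 8:
            raise ConfigError("n_timepoints must be >= 8")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if any(a < 0 for a in self.amp_by_group.values()):
            raise ConfigError("network amplitudes must be >= 0")
        if len(self.amp_by_group) != 2:
            raise ConfigError("amp_by_group must define exactly two group labels")
        if self.cardiac_hz <= 0 or self.resp_hz <= 0:
            raise ConfigError("physiological frequencies must be positive")
        r = self.node_radius_vox
        for c in self.node_centers:
            for axis in range(3):
                if not (r <= c[axis] <= self.grid_dims[axis] - 1 - r):
                    raise ConfigError(
                        f"node center {c} lies closer than node_radius={r} to the grid edge"
                    )

    @property
    def groups(self) -> tuple[str, str]:
        return tuple(sorted(self.amp_by_group))  # type: ignore[return-value]


@dataclass
class GroundTruth:
    """What was planted: per-voxel theoretical r, node masks, and the source."""

    true_r_map: np.ndarray
    node_masks: dict[str, np.ndarray]
    shared_source: np.ndarray

    def any_node_mask(self) -> np.ndarray:
        out = np.zeros(self.true_r_map.shape, dtype=bool)
        for m in self.node_masks.values():
            out |= m
        return out


def make_physio_traces(
    n_timepoints: int,
    tr_s: float,
    cardiac_hz: float = 1.0,
    resp_hz: float = 0.3,
    rng_seed: int = 0,
    jitter_sd: float = 0.05,
) -> PhysioTrace:
    """Per-volume cardiac/respiratory phase advancing at the nominal rate.

    Each phase increment is 2*pi*f*TR plus Gaussian jitter of SD
    ``jitter_sd`` radians (zero jitter gives the exact cumulative-sum
    phases). Deterministic for a fixed seed.
    """
    if n_timepoints < 2:
        raise ConfigError("n_timepoints must be >= 2")
    if cardiac_hz <= 0 or resp_hz <= 0:
        raise ConfigError("physiological frequencies must be positive")
    rng = np.random.default_rng(rng_seed)
    phases = []
    for f in (cardiac_hz, resp_hz):
        inc = 2 * np.pi * f * tr_s + rng.normal(0.0, jitter_sd, size=n_timepoints)
        inc[0] = 0.0  # phase starts at 0
        phases.append(np.mod(np.cumsum(inc), 2 * np.pi))
    return PhysioTrace(cardiac_phase=phases[0], resp_phase=phases[1])


def _sphere_mask(grid: tuple[int, int, int], center: tuple[int, int, int],
                 radius: int) -> np.ndarray:
    x, y, z = np.ogrid[: grid[0], : grid[1], : grid[2]]
    d2 = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
    return d2 <= radius**2


def make_network_source(n_timepoints: int, tr_s: float, max_hz: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Unit-variance latent source band-limited to (0, max_hz).

    Built by assigning random phases to every DFT bin strictly between DC
    and ``max_hz`` and inverse-transforming, then standardized to zero
    mean / unit (population) variance.
    """
    freqs = np.fft.rfftfreq(n_timepoints, d=tr_s)
    keep = (freqs > 0) & (freqs < max_hz)
    if not keep.any():
        raise ConfigError("no DFT bins below the source band limit; raise T or max_hz")
    spec = np.zeros(freqs.shape, dtype=complex)
    angles = rng.uniform(0, 2 * np.pi, size=int(keep.sum()))
    spec[keep] = np.exp(1j * angles)
    src = np.fft.irfft(spec, n=n_timepoints)
    src = src - src.mean()
    return src / src.std()


def generate_subject(
    config: SimulationConfig, group: str, rng_seed: int
) -> tuple[Image4D, PhysioTrace, GroundTruth]:
    """Simulate one subject's 4D series, physio trace, and ground truth."""
    if group not in config.amp_by_group:
        raise ValidationError(
            f"unknown group {group!r}; expected one of {sorted(config.amp_by_group)}"
        )
    a = float(config.amp_by_group[group])
    s = float(config.noise_sd)
    T = config.n_timepoints
    rng = np.random.default_rng(rng_seed)

    # independent child streams so each component is reproducible
    seed_src, seed_phys, seed_noise = [
        int(x) for x in np.random.SeedSequence(rng_seed).generate_state(3) % (2**31)
    ]
    source = make_network_source(T, config.tr_s, config.source_max_hz,
                                 np.random.default_rng(seed_src))
    physio = make_physio_traces(
        T, config.tr_s, config.cardiac_hz, config.resp_hz,
        rng_seed=seed_phys, jitter_sd=config.phase_jitter_sd,
    )

    node_masks = {
        f"node_{i}": _sphere_mask(config.grid_dims, c, config.node_radius_vox)
        for i, c in enumerate(config.node_centers)
    }
    in_node = np.zeros(config.grid_dims, dtype=bool)
    for m in node_masks.values():
        in_node |= m

    t_idx = np.arange(T, dtype=np.float64)
    confound = (
        config.physio_amp * (np.sin(physio.cardiac_phase) + np.sin(physio.resp_phase))
        + config.drift_slope * t_idx
    )

    noise_rng = np.random.default_rng(seed_noise)
    data = noise_rng.normal(0.0, s, size=config.grid_dims + (T,))
    data += confound  # broadcast over voxels
    data[in_node] += a * source

    true_r = np.zeros(config.grid_dims)
    true_r[in_node] = a / np.sqrt(a**2 + s**2)

    img = Image4D(data=data, voxel_size_mm=config.voxel_size_mm, tr_s=config.tr_s)
    return img, physio, GroundTruth(true_r_map=true_r, node_masks=node_masks,
                                    shared_source=source)


def subject_seeds(base_seed: int, n: int) -> list[int]:
    """Deterministic per-subject seeds derived from a base seed."""
    ss = np.random.SeedSequence(base_seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def generate_cohort(
    config: SimulationConfig,
    n_per_group: int,
    base_seed: int,
    out_dir: str | Path,
) -> pd.DataFrame:
    """Write a full two-group cohort to ``out_dir`` and return the manifest.

    Per subject: a 4D NIfTI image and a physio text file. Also written:
    the brain mask (all grid voxels), the ground-truth r map, node
    definitions as JSON, and the manifest TSV.
    """
    if n_per_group < 1:
        raise ConfigError("n_per_group must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    groups = config.groups
    n_total = 2 * n_per_group
    seeds = subject_seeds(base_seed, n_total)

    rows = []
    truth_written = False
    for i in range(n_total):
        group = groups[i // n_per_group]
        sid = f"sub-{i + 1:02d}"
        img, physio, truth = generate_subject(config, group, seeds[i])
        image_path = out / f"{sid}_bold.nii.gz"
        physio_path = out / f"{sid}_physio.txt"
        scio.write_image_4d(img, image_path)
        scio.write_physio(physio, physio_path)
        rows.append(
            {"subject_id": sid, "group": group, "image_path": str(image_path),
             "physio_path": str(physio_path), "rng_seed": seeds[i]}
        )
        if not truth_written:
            # geometry (node masks, true_r up to group amplitude) is shared
            scio.write_stat_map(
                StatMap(data=truth.true_r_map.copy(), kind="r", mask_applied=False),
                out / "ground_truth_r.nii.gz",
                voxel_size_mm=config.voxel_size_mm,
                extra={"group": group},
            )
            (out / "ground_truth_nodes.json").write_text(json.dumps({
                "node_centers": [list(c) for c in config.node_centers],
                "node_radius_vox": config.node_radius_vox,
                "amp_by_group": config.amp_by_group,
                "noise_sd": config.noise_sd,
            }, indent=2, sort_keys=True))
            truth_written = True

    mask = BrainMask(data=np.ones(config.grid_dims, dtype=bool))
    scio.write_mask(mask, out / "mask.nii.gz", voxel_size_mm=config.voxel_size_mm)

    manifest = pd.DataFrame(rows, columns=scio.MANIFEST_COLUMNS)
    scio.write_manifest(manifest, out / "manifest.tsv")
    return manifest


def default_roi_definition(config: SimulationConfig) -> "np.ndarray":
    """Label map marking each planted node as its own ROI (1-based labels)."""
    labels = np.zeros(config.grid_dims, dtype=np.int32)
    for i, c in enumerate(config.node_centers):
        labels[_sphere_mask(config.grid_dims, c, config.node_radius_vox)] = i + 1
    return labels
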