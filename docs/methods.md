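# Methods

This note records the model, the numerical choices, and what the synthetic
data do and do not establish.

## Pipeline model and assumptions

The per-subject analysis assumes resting-state volumes already share a
common grid (no registration is performed; images are only reoriented to
canonical axes on load). The connectivity statistic is the zero-lag
Pearson correlation with a seed reference — no lag search, no Fisher
transform. The stage order is fixed:

    nuisance regression → 2D in-plane Hamming → temporal low-pass
    → seed reference → correlation → Student's t → whole-brain z

Motion correction and slice-timing correction are out of scope; inputs
are assumed motion-free (the simulator generates none).

**Nuisance regression.** Physiological phases are accepted per volume
(slice-time resolution is not modelled). The design is an intercept plus
sine/cosine pairs of each phase at harmonics k = 1..m; m defaults to 2
(8 physiological regressors + intercept), the conventional order for this
kind of Fourier-basis correction. Residuals are computed via a QR
projection, so they are orthogonal to every design column at machine
precision; a rank-deficient design is rejected with the dependent columns
named.

**Spatial filter.** The Hamming filter is k-space apodization: each axial
slice's 2D DFT is multiplied by the separable window
`w(k) = 0.54 + 0.46·cos(π·|k|/k_max)` on DC-centred frequency indices,
with w(0) = 1, so slice means are preserved exactly. This is the
functional-CNR usage of the filter; applying it in image space as a
convolution kernel would be equivalent. The mask does not restrict the
operation (k-space filtering is non-local).

**Temporal filter.** "Remove all fluctuations above 0.08 Hz" is taken
literally: a hard projection that zeroes every DFT bin above the cutoff
and keeps bins at or below it (DC included). The projection is zero-phase
and idempotent, unlike an IIR/FIR realization. The cutoff must sit below
the Nyquist frequency 1/(2·TR) ≈ 0.179 Hz at TR = 2.8 s.

**Seed and reference.** The 9-voxel seed is a deterministic 3×3
single-slice block at a user-given centre; the interactive anatomical
refinement used when seeds are placed on real anatomy is replaced by the
explicit coordinate, which keeps runs reproducible. The reference is the
linearly detrended mean of the 9 series (least squares against intercept
+ time index 0..T−1; orthogonality of the residual is the contract).

**Degrees of freedom.** t = r·√(dof/(1−r²)) with dof = T − 2 by default
(130 at T = 132). Temporal filtering reduces the *effective* dof — after
the 0.08 Hz projection roughly 45% of the spectral bins remain — so a
fixed user-supplied dof is supported. Because the subsequent whole-brain
standardization rescales the t map anyway, the dof choice does not affect
the z-maps' ordering, only the intermediate t values. |r| is clipped at
1 − 1e-12 before conversion so correlations of ±1 stay finite.

**Standardization.** z = (t − mean)/SD over in-mask voxels, population SD
(divide by N) by default since the map is treated as a whole-brain
distribution; the sample convention is switchable and recorded in the
output sidecar. The operation is idempotent and affine-invariant.

**Group contrast.** Two difference modes: `naive_diff` (raw difference of
group mean z-maps) and `standardized_diff` (divided by √(1/n_a + 1/n_b)),
the default, which is a proper z-statistic under the null for
unit-variance subject maps and therefore the mode under which the
single-voxel p < 0.05 threshold (z ≈ 1.95996 two-sided) is calibrated.
Cluster extent "> 30" is read strictly: the default minimum surviving
size is 31 voxels. Connected components use face adjacency
(6-connectivity), the most conservative standard neighbourhood; edges and
corners are selectable. Positive and negative suprathreshold voxels are
labelled separately so opposite-signed adjacent clusters never merge.

**ROI tables.** Per-subject region summaries are computed over voxels
with z ≥ z_floor; z_floor defaults to 2.3, consistent with per-subject
region minima clustering near 2.4–2.5 in published tables of this design,
and is exposed as a parameter that users should set deliberately. Group
rows use the sample (n−1) SD — the convention is pinned by a worked check:
the sample SD of (2.62, 2.83, 3.00) rounds to 0.19 where the population
SD would give 0.16 — and report output rounds half-up to 2 decimals.

## Synthetic cohorts

The generator emulates a small two-group resting-state study: 132 volumes
at TR = 2.8 s, 3 subjects per group, two groups differing **only** in
network amplitude, so any detected contrast is attributable to
connectivity. Voxel series are

    y_v(t) = a·n(t)·[v ∈ node] + c·(sin φ_c + sin φ_r) + d·t + s·ε_v(t)

with n(t) a unit-variance source synthesized from random-phase DFT bins
strictly below 0.08 Hz (the temporal filter preserves it by
construction), φ cardiac/respiratory phases advancing at 1.0 / 0.3 Hz
with 0.05 rad/volume jitter, and ε white Gaussian noise. The planted
voxel–source correlation in node voxels is exactly a/√(a² + s²).

Defaults: grid 24×24×16 (desk-scale, not a brain), three spherical nodes
of radius 2 (33 voxels each — deliberately above the 31-voxel cluster
requirement), noise SD s = 1.0, amplitudes 0.3 (head-trauma) and 0.8
(no-head-trauma), physiological amplitude c = 0.1, drift d = 0.005 per
volume. The group amplitudes are an assumption, not an estimate — no
effect size for the group difference is available to calibrate against —
chosen to give planted correlations of ≈ 0.29 and ≈ 0.62, i.e. a clearly
detectable but not degenerate contrast at n = 3 per group. The brain mask
is the full grid: a shaped mask adds nothing at this scale and the
standardization contract is mask-relative.

What the simulator does **not** model: head motion, registration error,
spatially correlated physiological noise, susceptibility artifacts,
multiband reconstruction physics, or non-spherical network geometry.
Passing recovery tests therefore demonstrates the pipeline's statistical
logic, not robustness to real-scanner artifacts.

Two consequences of the signal model worth knowing:

* The drift and physio confounds are shared by all voxels of a subject,
  so one subject's voxels carry a common chance correlation with that
  subject's source of order ±0.05. Off-node correlations are centred on
  zero across subjects (ensemble property), not exactly within each one.
* Seed voxels correlate with their own 9-voxel average even for pure
  noise, so an amplitude-0 subject's z-map peaks at the seed (|z| ≈ 7)
  while the rest of the map follows Gaussian order statistics.

## Numerical choices

* Detrending/regression by least squares (QR); residual orthogonality to
  the design < 1e-8 relative is asserted in tests.
* All filters are linear; superposition holds to 1e-8 relative, and the
  temporal projection is idempotent to 1e-10.
* Zero-variance voxels inside the mask get r = 0 and a QC count instead
  of aborting the run; clipped |r| = 1 correlations are likewise counted.
* Off-mask voxels are NaN in stat maps and NaN survives NIfTI round
  trips; stat-map kind and provenance travel in JSON sidecars.
* Determinism: every stochastic quantity is a pure function of (config,
  seed); per-subject seeds derive from the base seed via seed-sequence
  spawning and stay below 2^31. Reruns produce byte-identical data files
  (provenance records carry a timestamp and are metadata).
* Rounding for printed tables is half-up via decimal arithmetic, not
  banker's rounding.

## Problem sizes used in validation

Oracle-equivalence checks run on 8×8×8×40 images against naive loops;
recovery checks run the full pipeline on the default 24×24×16×132 grid
with 3 subjects per group, 20 replicates per condition (cluster recovery
with amplitudes 0.3 vs 0.8; false-positive control with equal
amplitudes). These sizes were chosen so the entire suite validates the
statistical behaviour in minutes on one CPU while keeping ≥ 30-voxel
clusters and ≥ 99 node voxels in play.

## Known limitations

* The effective dof after temporal filtering is smaller than the nominal
  T − 2; absolute t values are therefore optimistic (z-maps are
  unaffected by this scaling).
* The cluster-extent threshold controls false positives empirically at
  this grid and smoothing level (zero surviving null clusters in 20/20
  replicates) but carries no analytic family-wise error guarantee; no
  permutation or FDR correction is implemented.
* With n = 3 per group, the standardized difference is a large-sample
  approximation used descriptively, as in the study design it mirrors —
  not a calibrated small-sample test.
* ROI summaries depend on a suprathreshold floor whose field-standard
  value is not settled; results should state the floor used.
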