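# Methods

This note documents the models, conventions and numerical choices behind
`brightpath`, and what the synthetic-data tests do and do not establish.

## Connectivity-guided target identification

The individualized stimulation target is the voxel of the left middle
frontal gyrus (lMFG) where outgoing effective connectivity from the right
anterior insula (rAI; 6-mm sphere at MNI x=30, y=24, z=−14) peaks.

**Effective connectivity.** For a seed series x and a voxel series y,
both standardized to zero mean and unit variance, we fit the bivariate
first-order model

    y_t = c + a·y_{t−1} + b·x_{t−1} + e_t,   t = 2..T

by ordinary least squares and take the signed path coefficient b as the
x→y effective connectivity. "Coefficient-based" Granger analysis of this
form reports the signed lagged regression weight rather than a variance
ratio; standardizing both series makes b comparable across voxels.
Voxelwise coefficients over the search mask are then z-scored across
in-mask voxels, z_v = (b_v − mean b)/sd b, because the downstream
thresholding and cluster logic operate on a Z-scale map. The search mask
is the intersection of the lMFG region with the suprathreshold support of
the selected network component.

**Component selection.** The spatial ICA decomposition itself is
delegated to external tools; this package consumes z-scored component
maps. Each candidate is filtered by zeroing values below 1.96 and the
component whose filtered map has the highest Pearson correlation with the
left central-executive-network template wins. Zero-variance filtered
maps rank as −∞; if every candidate is degenerate the selection errors
out.

**Target extraction.** Suprathreshold (z > 1.96) in-mask voxels are
clustered with 26-connectivity; the target is the voxel of global
maximum z, which necessarily lies in the top cluster. "Most significant
cluster" is therefore operationalized as "cluster containing the global
maximum", and "peak" as the maximum-z voxel (not a center of mass). Ties
break in lexicographic voxel order so reruns are bit-identical.

**Denoising support.** Only the steps that feed the connectivity stage
are implemented: WM/CSF probability maps are binarized at 98% and eroded
with a discrete spherical kernel of radius 2 voxels; the mean WM and CSF
series (plus intercept) are regressed out of every voxel; and a hard
frequency-domain high-pass at 0.01 Hz removes the DC component and all
bins strictly below cutoff. The hard cutoff was chosen over a smooth
filter because it is exactly testable against a discrete Fourier oracle;
its ringing behaviour is irrelevant to the lag-1 regression used here.
Slice timing, motion correction, distortion correction, smoothing and
ICA denoising are out of scope and assumed done upstream.

**Standard (rTMS) target.** The F3 scalp position in MNI152 space,
(−49, 51, 40) mm, is projected to the nearest voxel of the brain mask in
millimetre (affine-aware) distance. The protocol's reference answer for
this projection against the standard-space template, (−41, 43, 32) mm,
requires the MNI152 brain mask and is documented here as an external
validation to run against that template; it is deliberately excluded
from the unit tests, which verify the projection operator against
exhaustive-scan oracles on synthetic masks instead.

## Coil-pose geometry

**NLR frame.** The head-fixed frame is built from three fiducials: the
nasion N and the left/right preauricular points L, R. The origin O is
the orthogonal projection of N onto the line LR; the x-axis points to the
nasion, y to the left ear, z to the vertex. In NLR coordinates,
O→(0,0,0), N→(‖N−O‖,0,0), L→(0,‖L−O‖,0), R→(0,−‖R−O‖,0). A least-squares
rigid (Kabsch) fit of the four correspondences gives the anatomical→NLR
map; for anatomically plausible fiducials (nasion projecting between the
ears) the assignment is an exact isometry and the fit has zero residual.
Equal weighting of the four pairs is used. Landmarks are assumed
available (defacing preserves nose bridge and ears).

**Scalp projection and orientation.** The brain target is mapped to NLR
space and projected to the nearest mesh vertex. The coil z-axis c_z is
the outward unit normal there (area-weighted mean of incident face
normals, oriented away from the mesh centroid). The coil y-axis must be
orthogonal to c_z while its projection onto the NLR xy-plane makes a 45°
angle with the midsagittal (x) axis: writing the in-plane direction
u = (cos 45°, sin 45°), we take c_y ∝ (u_x, u_y, h) with
h = −(u_x z_1 + u_y z_2)/z_3 forced by orthogonality. This satisfies the
projected-angle constraint exactly (to floating-point precision) for
every normal that is not horizontal. c_x = c_y × c_z completes a
right-handed orthonormal basis. The anterior-left (+45°) solution is the
default; the constraint admits a mirrored −45° solution, selectable via
the angle parameter, since the protocol's choice between the two is not
observable from the geometry alone. A horizontal normal with a blocked
handle direction falls back to the mirrored solution and otherwise
raises; such normals do not occur at prefrontal scalp sites.

**Quaternion export.** Rotations are exported scalar-first (w, x, y, z),
Hamilton convention, normalized, with w ≥ 0 to fix the double-cover sign.
Plans are versioned JSON (`brightpath-plan/1`) with the brain target,
scalp vertex, rotation matrix, quaternion, NLR landmark coordinates and a
provenance block (software version + configuration hash), and round-trip
bit-exactly.

**Head mesh extraction.** When a mesh is not supplied, one can be
extracted from a head volume by thresholding (automatic default: the
midpoint of the robust 1st/99th intensity percentiles, overridable — the
manual override mirrors the protocol's visual re-thresholding loop),
marching cubes, and uniform Laplacian smoothing (v ← v + λ(mean of
neighbours − v), λ = 0.5) for a default of 100 steps. Smoothing
monotonically shrinks surface area on convex fixtures, which the tests
exploit.

## BOLD motion QC

Framewise displacement uses the Power convention:
FD_t = Σ|Δtranslation| + r·Σ|Δrotation| with r = 50 mm (field-standard
head radius; the protocol does not state one) and FD_1 = 0. A scan fails
if any FD exceeds 3 mm or the mean FD (including the zero first frame)
exceeds 1 mm; the report lists every violated rule plus the visual
checks (artifacts, carpet-plot intensity changes, coverage, incidental
findings) that remain a manual checklist.

## MEGA-PRESS preprocessing

FIDs are complex time series at dwell time Δt; spectra are
`fftshift(fft(fid))` and the chemical-shift axis is
ppm = 4.68 + f/f0 with f0 the spectrometer frequency in MHz (water at
4.68 ppm).

* **Eddy-current correction** is Klose-style water-phase subtraction:
  fid_t·exp(−i·arg(water_t)). Pointwise magnitude is exactly preserved;
  near-zero water samples carry the last valid phase forward.
* **Spectral registration** aligns each FID to the mean OFF spectrum by
  minimizing Σ|fid·e^{i(2πft+φ)} − ref|² over (f, φ) in the time domain.
  Because the cost is oscillatory in f (local minima ≈ 1/T apart), a
  coarse grid over ±20 Hz with the closed-form optimal phase per grid
  point seeds a Levenberg–Marquardt refinement. At time-domain SNR 50
  the per-draw frequency error is ≈ 0.03 Hz (1 sd).
* **Outlier rejection** computes each spectrum's mean square error
  against the mean spectrum over the choline window (3.1–3.3 ppm,
  configurable) and rejects spectra above mean + 3 sd of the
  across-spectra MSE distribution, in a single pass (iterative
  re-estimation is a possible refinement, not implemented).
* **QC gates:** water linewidth is the FWHM of the zero-order-phased
  absorption water peak by linear interpolation at half height (the
  magnitude-mode width of a Lorentzian is √3 larger and would not match
  the nominal linewidth the 13 Hz threshold refers to); OFF-spectrum SNR
  (NAA-window peak magnitude over the sd of the real part in the
  signal-free low-ppm tail) is gated at 3 sd below the cohort mean.

## Trial power calculators

**Repeated-follow-up mean difference.** The outcome is the mean of k = 3
follow-up HDRS-17 scores; with inter-follow-up correlation r_f its
variance is σ²(1+(k−1)r_f)/k. Baseline adjustment is modelled as ANCOVA
variance reduction through the baseline–follow-up-mean correlation
r_bm = r_b√(k/(1+(k−1)r_f)), multiplying the variance by (1−r_bm²).
Dropout reduces n uniformly before analysis, and the per-arm analyzed
size is rounded to a whole participant:
n_arm = round(n_total(1−dropout)/2). With se = sd_adj·√(2/n_arm), power
is Φ(δ/se − z_c) + Φ(−δ/se − z_c) (normal approximation; both rejection
tails counted, so a null effect returns exactly α). Defaults: δ = 3
points, σ = 8, r_f = 0.7, r_b = 0.27, dropout 20%, α = .05 two-sided.
A noncentral-t variant is available behind `use_t` and runs ~0.3 points
lower. The Monte-Carlo cross-check simulates correlated
baseline+follow-up vectors per arm and runs the two-group ANCOVA.

**Fisher-z correlation power.** z(ρ) = atanh ρ with sampling sd
1/√(n−3); power = Φ(|z(ρ1)−z(ρ0)|√(n−3) − z_c) (+ the opposite tail when
two-sided). The minimum detectable correlation inverts the dominant-tail
formula: |ρ| = tanh(z(ρ0) + (z_c + z_power)/√(n−3)), exact (rounding is
presentation-only).

## Synthetic fixtures

The generators produce the smallest inputs that exercise each stage with
known ground truth; all are deterministic under a fixed seed.

* **VAR-BOLD** (default 24×24×18 voxels of 3 mm, T = 240 at TR 2 s,
  matching the acquisition the pipeline is built for): the seed sphere
  carries a common white-noise series (per-voxel jitter sd 0.1), exactly
  one search-block voxel follows y_t = b·x_{t−1} + ε with b = 0.5 and
  ε ~ N(0,1), and everything else is white noise. WM/CSF blocks carry
  shared drift signals. Component maps are suprathreshold blobs (winner
  over the search block, a decoy elsewhere, one pure-noise map).
* **Head fixtures** are icospheres (optionally anisotropically scaled
  into ellipsoids) with fiducials at the analytic +x/±y surface points
  and closed-form normals.
* **Motion traces** are cumulative Gaussian jitter (0.02 mm / 0.0002 rad
  per frame) with optional sustained translation steps of known size.
* **MEGA-PRESS sets** are sums of Lorentzians (Cho 3.2, Cr 3.0, NAA
  2.0 ppm; edited resonance at 3.0 ppm in ON only) with per-acquisition
  frequency/phase jitter and complex white noise scaled so that
  |signal(t=0)|/sd = SNR (time-domain convention).

None of these model realistic anatomy, physiological noise spectra,
spatial autocorrelation, ICA estimation error, or scanner drift, so
passing tests demonstrate algorithmic correctness under the stated
generative assumptions — not performance on acquired data. In
particular, planted-causality recovery rates on the VAR fixture are an
upper bound on what heavier-tailed, autocorrelated real BOLD noise would
allow.

## Problem sizes and numerics

Tests run the VAR fixture at its default size (recovery checks use 100
seeds), the Monte-Carlo power oracles at 40 000 simulated trials
(standard error ≈ 0.2 points), the geometry properties at 1 000 random
normals, and the registration recovery at 25 noise draws (median error
reported). Tolerances: orthonormality and standardization identities at
1e−12, quaternion round trips at 1e−9, rigid-motion invariance at 1e−6,
stochastic recoveries at the bounds stated in the tests. Degenerate
inputs (collinear fiducials, zero-variance series, empty masks,
sub-threshold maps, horizontal normals) raise typed errors rather than
returning silently wrong results, except mask erosion, which returns an
empty mask with a warning because downstream behaviour is the caller's
protocol decision.
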