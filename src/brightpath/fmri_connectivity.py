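"""Effective-connectivity target identification from resting-state BOLD.

The individualized stimulation target (for connectivity-guided iTBS) is
the voxel in the left middle frontal gyrus where outgoing effective
connectivity from the right anterior insula (rAI) peaks. Effective
connectivity is measured by a bivariate first-order Granger model on
standardized series: regress y_t on [1, y_{t-1}, x_{t-1}] and keep the
signed path coefficient b on x_{t-1}. Voxelwise b values over a search
mask are z-standardized across the mask; the target is the peak of the
suprathreshold cluster containing the global maximum.

The standard (non-individualized) rTMS target is simply the brain voxel
nearest the F3 scalp position.

Minimal denoising support is included: nuisance-mask construction
(probability threshold + spherical erosion), mean WM/CSF time-series
regression, and a hard frequency-domain high-pass. The spatial ICA
decomposition itself is delegated to external tools; this module consumes
its z-scored component maps and selects the one matching a network
template.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "BoldSeries",
    "SpatialMap",
    "VoxelMask",
    "BrainTarget",
    "NoSignificantTargetError",
    "binarize_and_erode_mask",
    "regress_nuisance",
    "highpass",
    "select_component",
    "seed_series",
    "granger_first_order",
    "gca_zmap",
    "peak_cluster_target",
    "project_point_to_mask",
    "sphere_mask",
]

logger = logging.getLogger(__name__)

DEFAULT_Z_THRESHOLD = 1.96
F3_MNI_MM = (-49.0, 51.0, 40.0)  # scalp F3 position in MNI152 space
RAI_CENTER_MNI_MM = (30.0, 24.0, -14.0)  # right anterior insula seed center
RAI_RADIUS_MM = 6.0


class NoSignificantTargetError(RuntimeError):
    """No in-mask voxel exceeds the z threshold; caller falls back per protocol."""


@dataclass
class BoldSeries:
    """4-D BOLD signal (x, y, z, t) with voxel geometry and repetition time."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    tr: float
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4-D (x, y, z, t)")
        if self.frame_count < 3:
            raise ValueError("need at least 3 frames")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        if not np.isfinite(self.data).all():
            raise ValueError("BOLD data contains non-finite values")
        if self.affine is None:
            self.affine = np.diag([*self.voxel_size, 1.0])

    @property
    def frame_count(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @classmethod
    def from_nifti(cls, path: str | Path, tr: float | None = None) -> "BoldSeries":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()
        tr = float(tr if tr is not None else zooms[3])
        return cls(
            data=np.asanyarray(img.dataobj, dtype=float),
            voxel_size=tuple(float(z) for z in zooms[:3]),
            tr=tr,
            affine=np.asarray(img.affine),
        )

    def to_nifti(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms((*self.voxel_size, self.tr))
        nib.save(img, str(path))


@dataclass
class SpatialMap:
    """3-D scalar grid aligned with a BOLD series or anatomical volume."""

    values: np.ndarray
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("spatial map must be 3-D")

    @classmethod
    def from_nifti(cls, path: str | Path) -> "SpatialMap":
        img = nib.load(str(path))
        return cls(np.asanyarray(img.dataobj, dtype=float), np.asarray(img.affine))


@dataclass
class VoxelMask:
    """3-D boolean grid with a semantic label."""

    values: np.ndarray
    label: str = "brain"
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError("mask must be 3-D")

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    @classmethod
    def from_nifti(cls, path: str | Path, label: str = "brain") -> "VoxelMask":
        img = nib.load(str(path))
        return cls(np.asanyarray(img.dataobj) > 0.5, label, np.asarray(img.affine))


@dataclass
class BrainTarget:
    voxel_index: tuple[int, int, int]
    world_mm: tuple[float, float, float]
    kind: str  # "cgiTBS" | "rTMS"
    peak_z: float | None = None


def _voxel_to_mm(index: np.ndarray, affine: np.ndarray) -> np.ndarray:
    return (affine @ np.append(np.asarray(index, dtype=float), 1.0))[:3]


def sphere_mask(
    shape: tuple[int, int, int],
    center_voxel: tuple[float, float, float],
    radius_mm: float,
    voxel_size: tuple[float, float, float],
    label: str = "rAI_sphere",
) -> VoxelMask:
    """All voxels whose center lies within ``radius_mm`` of the given center."""
    grids = np.indices(shape).astype(float)
    d2 = sum(
        ((grids[i] - center_voxel[i]) * voxel_size[i]) ** 2 for i in range(3)
    )
    values = d2 <= radius_mm**2
    if not values.any():
        raise ValueError("sphere mask contains no voxels")
    return VoxelMask(values, label=label)


# ---------------------------------------------------------------------------
# Nuisance-mask construction and denoising
# ---------------------------------------------------------------------------

def binarize_and_erode_mask(
    prob_map: SpatialMap, threshold: float = 0.98, radius_voxels: int = 2
) -> VoxelMask:
    """Threshold a tissue-probability map and erode with a spherical kernel.

    Voxels with probability >= threshold are kept, then morphologically
    eroded by a discrete ball of the given voxel radius. An empty result
    is returned with a warning rather than raised: the caller decides.
    """
    values = prob_map.values
    if values.min() < 0 or values.max() > 1:
        raise ValueError("probability map values must lie in [0, 1]")
    binary = values >= threshold
    if radius_voxels > 0 and binary.any():
        grids = np.indices((2 * radius_voxels + 1,) * 3) - radius_voxels
        ball = (grids**2).sum(axis=0) <= radius_voxels**2
        binary = ndimage.binary_erosion(binary, structure=ball)
    if not binary.any():
        logger.warning("binarize_and_erode_mask produced an empty mask")
    return VoxelMask(binary, label="nuisance", affine=prob_map.affine)


def regress_nuisance(bold: BoldSeries, wm: VoxelMask, csf: VoxelMask) -> BoldSeries:
    """Regress mean WM and CSF series (plus intercept) out of every voxel.

    Each voxel time series is replaced by its least-squares residual. If
    the WM and CSF mean series are collinear one regressor is dropped.
    """
    for mask in (wm, csf):
        if mask.values.shape != bold.grid_shape:
            raise ValueError(f"{mask.label} mask grid does not match BOLD grid")
        if mask.n_voxels == 0:
            raise ValueError(f"{mask.label} mask is empty")
    t = bold.frame_count
    wm_series = bold.data[wm.values].mean(axis=0)
    csf_series = bold.data[csf.values].mean(axis=0)
    design = np.column_stack([np.ones(t), wm_series, csf_series])
    if np.linalg.matrix_rank(design) < 3:
        logger.warning("WM and CSF series collinear; dropping the CSF regressor")
        design = design[:, :2]
    flat = bold.data.reshape(-1, t).T  # (t, n_voxels)
    coeffs, *_ = np.linalg.lstsq(design, flat, rcond=None)
    residuals = flat - design @ coeffs
    return BoldSeries(
        data=residuals.T.reshape(bold.data.shape),
        voxel_size=bold.voxel_size,
        tr=bold.tr,
        affine=bold.affine,
    )


def highpass(bold: BoldSeries, cutoff_hz: float = 0.01) -> BoldSeries:
    """Hard frequency-domain high-pass: zero all components below cutoff.

    The DC component is always removed; output length is unchanged.
    """
    if cutoff_hz <= 0:
        raise ValueError("cutoff must be positive")
    t = bold.frame_count
    nyquist = 0.5 / bold.tr
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz at or above Nyquist {nyquist} Hz")
    freqs = np.fft.rfftfreq(t, bold.tr)
    keep = freqs >= cutoff_hz
    spectra = np.fft.rfft(bold.data, axis=3)
    spectra[..., ~keep] = 0
    filtered = np.fft.irfft(spectra, n=t, axis=3)
    return BoldSeries(filtered, bold.voxel_size, bold.tr, bold.affine)


# ---------------------------------------------------------------------------
# Component selection and seed extraction
# ---------------------------------------------------------------------------

def select_component(
    components: list[SpatialMap],
    template: SpatialMap,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> tuple[int, SpatialMap]:
    """Pick the z-scored ICA component best matching a network template.

    Each component is copied with values below ``z_threshold`` zeroed;
    the winner maximizes Pearson correlation between the filtered map and
    the template. Zero-variance filtered components rank as -inf.
    """
    if not components:
        raise ValueError("no candidate components")
    tvals = template.values.ravel()
    best_idx, best_r, best_map = -1, -np.inf, None
    for i, comp in enumerate(components):
        if comp.values.shape != template.values.shape:
            raise ValueError(f"component {i} grid does not match the template")
        filtered = np.where(comp.values >= z_threshold, comp.values, 0.0)
        fvals = filtered.ravel()
        if fvals.std() == 0 or tvals.std() == 0:
            r = -np.inf
        else:
            r = float(np.corrcoef(fvals, tvals)[0, 1])
        if r > best_r:
            best_idx, best_r, best_map = i, r, filtered
    if best_idx < 0 or not np.isfinite(best_r):
        raise ValueError("all filtered components are degenerate (zero variance)")
    return best_idx, SpatialMap(best_map, template.affine)


def seed_series(bold: BoldSeries, roi: VoxelMask) -> np.ndarray:
    """Per-frame mean BOLD signal over the ROI voxels."""
    if roi.values.shape != bold.grid_shape:
        raise ValueError("ROI grid does not match BOLD grid")
    if roi.n_voxels == 0:
        raise ValueError("empty ROI")
    return bold.data[roi.values].mean(axis=0)


# ---------------------------------------------------------------------------
# Granger causality
# ---------------------------------------------------------------------------

def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("zero-variance series")
    return (x - x.mean()) / sd


def granger_first_order(x: np.ndarray, y: np.ndarray) -> float:
    """Signed first-order Granger path coefficient from x to y.

    Both series are standardized to zero mean / unit variance; then
    y_t = c + a y_{t-1} + b x_{t-1} + e is fit by OLS over t = 2..T and
    the coefficient b is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    if len(x) < 10:
        raise ValueError("need at least 10 time points")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("series contain non-finite values")
    xs, ys = _standardize(x), _standardize(y)
    design = np.column_stack([np.ones(len(x) - 1), ys[:-1], xs[:-1]])
    if np.linalg.matrix_rank(design) < 3:
        raise np.linalg.LinAlgError("rank-deficient Granger design (x collinear with y)")
    coeffs, *_ = np.linalg.lstsq(design, ys[1:], rcond=None)
    return float(coeffs[2])


def gca_zmap(bold: BoldSeries, seed: np.ndarray, search_mask: VoxelMask) -> SpatialMap:
    """Voxelwise seed->voxel Granger coefficients, z-scored across the mask.

    For every in-mask voxel the first-order path coefficient b from the
    seed series to the voxel series is computed (same model as
    :func:`granger_first_order`, batched), then standardized across
    in-mask voxels: z_v = (b_v - mean b) / sd b. Out-of-mask voxels are 0.
    """
    if search_mask.n_voxels == 0:
        raise ValueError("empty search mask")
    seed = np.asarray(seed, dtype=float)
    if seed.shape[0] != bold.frame_count:
        raise ValueError("seed series length does not match frame count")
    xs = _standardize(seed)
    series = bold.data[search_mask.values]  # (n_voxels, t)
    mu = series.mean(axis=1, keepdims=True)
    sd = series.std(axis=1, ddof=0, keepdims=True)
    if (sd == 0).any():
        raise ValueError("zero-variance voxel series inside the search mask")
    ys = (series - mu) / sd

    # batched per-voxel OLS of y_t on [1, y_{t-1}, x_{t-1}] via normal equations
    yl = ys[:, :-1]
    yt = ys[:, 1:]
    xl = xs[:-1]
    t = yl.shape[1]
    n = yl.shape[0]
    gram = np.empty((n, 3, 3))
    gram[:, 0, 0] = t
    gram[:, 0, 1] = gram[:, 1, 0] = yl.sum(axis=1)
    gram[:, 0, 2] = gram[:, 2, 0] = xl.sum()
    gram[:, 1, 1] = (yl**2).sum(axis=1)
    gram[:, 1, 2] = gram[:, 2, 1] = yl @ xl
    gram[:, 2, 2] = (xl**2).sum()
    rhs = np.empty((n, 3))
    rhs[:, 0] = yt.sum(axis=1)
    rhs[:, 1] = (yl * yt).sum(axis=1)
    rhs[:, 2] = yt @ xl
    coeffs = np.linalg.solve(gram, rhs[:, :, None])[:, :, 0]
    b = coeffs[:, 2]

    sd_b = b.std(ddof=0)
    if sd_b == 0:
        raise ValueError("all in-mask coefficients identical; z-map undefined")
    z = (b - b.mean()) / sd_b
    out = np.zeros(bold.grid_shape)
    out[search_mask.values] = z
    return SpatialMap(out, bold.affine)


# ---------------------------------------------------------------------------
# Target extraction
# ---------------------------------------------------------------------------

def peak_cluster_target(
    zmap: SpatialMap,
    mask: VoxelMask,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    affine: np.ndarray | None = None,
) -> BrainTarget:
    """Peak voxel of the most significant suprathreshold cluster.

    Clusters are 26-connected components of in-mask voxels with
    z > threshold; the returned voxel is the global z maximum, which by
    construction lies in the most significant cluster. Ties break in
    lexicographic voxel order.
    """
    if zmap.values.shape != mask.values.shape:
        raise ValueError("z-map and mask grids differ")
    supra = (zmap.values > z_threshold) & mask.values
    if not supra.any():
        raise NoSignificantTargetError(
            f"no in-mask voxel exceeds z = {z_threshold}; fall back per protocol"
        )
    # global max over suprathreshold voxels; np.argmax is lexicographic-first
    masked = np.where(supra, zmap.values, -np.inf)
    flat_idx = int(np.argmax(masked))
    voxel = np.unravel_index(flat_idx, zmap.values.shape)
    labels, _ = ndimage.label(supra, structure=np.ones((3, 3, 3), dtype=int))
    assert labels[voxel] > 0
    aff = affine if affine is not None else (zmap.affine if zmap.affine is not None else np.eye(4))
    world = _voxel_to_mm(np.array(voxel), aff)
    return BrainTarget(
        voxel_index=tuple(int(v) for v in voxel),
        world_mm=tuple(float(v) for v in world),
        kind="cgiTBS",
        peak_z=float(zmap.values[voxel]),
    )


def project_point_to_mask(
    point_mm: tuple[float, float, float],
    mask: VoxelMask,
    voxel_size: tuple[float, float, float] | None = None,
    affine: np.ndarray | None = None,
    kind: str = "rTMS",
) -> BrainTarget:
    """In-mask voxel nearest (in mm) to a world-space point; lexicographic ties.

    Either an affine or a voxel size must be supplied to place voxel
    centers in world space.
    """
    if mask.n_voxels == 0:
        raise ValueError("empty mask")
    if affine is None:
        affine = mask.affine
    if affine is None:
        if voxel_size is None:
            raise ValueError("need voxel_size or affine")
        affine = np.diag([*voxel_size, 1.0])
    idx = np.argwhere(mask.values)
    homog = np.column_stack([idx.astype(float), np.ones(len(idx))])
    world = homog @ affine.T
    d2 = np.sum((world[:, :3] - np.asarray(point_mm, dtype=float)) ** 2, axis=1)
    # argwhere returns voxels in lexicographic order; argmin takes the first tie
    best = idx[int(np.argmin(d2))]
    return BrainTarget(
        voxel_index=tuple(int(v) for v in best),
        world_mm=tuple(float(v) for v in _voxel_to_mm(best, affine)),
        kind=kind,
    )
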