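"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator is deterministic under a fixed seed and emulates just
enough structure for the corresponding stage to be testable end to end:

* ``make_var_bold`` — a small 4-D BOLD volume in which the mean series of
  an insula-like seed sphere drives exactly one voxel of the frontal
  search region through a first-order VAR coupling; every other voxel is
  white noise. The planted voxel is the ground-truth connectivity target.
* ``make_head_fixture`` — a sphere or ellipsoid head mesh with fiducials
  at analytic positions and closed-form surface normals.
* ``make_motion_trace`` — a realignment-parameter table with optional
  translation spikes of known size.
* ``make_megapress`` — interleaved ON/OFF Lorentzian FIDs (Cho, Cr, NAA,
  plus an edited resonance present only in ON) with configurable
  frequency/phase jitter and noise, and a water reference.

None of this models realistic anatomy or scanner physics; noise is white
(plus Lorentzian decay for MRS) by design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .bold_qc import MotionTrace
from .fmri_connectivity import BoldSeries, SpatialMap, VoxelMask, sphere_mask
from .mrs_prep import WATER_PPM, EditedSpectrumSet
from .target_geometry import HeadModel, LandmarkSet

__all__ = [
    "FixtureSpec",
    "VarBoldFixture",
    "HeadFixture",
    "make_var_bold",
    "make_head_fixture",
    "make_motion_trace",
    "make_megapress",
]


@dataclass
class FixtureSpec:
    """Shared knobs for the VAR-BOLD fixture."""

    random_seed: int = 0
    grid_shape: tuple[int, int, int] = (24, 24, 18)
    n_frames: int = 240
    tr: float = 2.0
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)
    coupling: float = 0.5  # VAR coefficient seed -> planted voxel
    noise_sd: float = 1.0
    seed_voxel_noise_sd: float = 0.1  # per-voxel jitter inside the seed sphere


@dataclass
class VarBoldFixture:
    bold: BoldSeries
    rai: VoxelMask
    lmfg: VoxelMask
    wm: VoxelMask
    csf: VoxelMask
    components: list[SpatialMap]
    template: SpatialMap
    true_target_voxel: tuple[int, int, int]
    seed_series_truth: np.ndarray


@dataclass
class HeadFixture:
    mesh: HeadModel
    landmarks: LandmarkSet
    center: np.ndarray
    semiaxes: np.ndarray

    def analytic_normal(self, point: np.ndarray) -> np.ndarray:
        """Outward unit normal of the implicit surface at a surface point."""
        g = 2 * (np.asarray(point, dtype=float) - self.center) / self.semiaxes**2
        return g / np.linalg.norm(g)


def make_var_bold(spec: FixtureSpec | None = None) -> VarBoldFixture:
    """BOLD volume with one planted seed->voxel causal path.

    Geometry (all in voxel units on the default 24 x 24 x 18 grid):
    the seed sphere sits in the posterior-right quadrant, the frontal
    search block (where the planted voxel lives) in the anterior-left
    quadrant, and WM/CSF nuisance blocks near the center. The winning
    "component" map is suprathreshold exactly over the search block, so
    component selection recovers it; two decoy components are included.
    """
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.random_seed)
    shape, t = spec.grid_shape, spec.n_frames

    data = rng.normal(0.0, spec.noise_sd, size=(*shape, t))

    # seed sphere: every voxel carries the common series plus small jitter
    seed_center = (int(shape[0] * 0.75), int(shape[1] * 0.33), int(shape[2] * 0.33))
    rai = sphere_mask(shape, seed_center, 6.0, spec.voxel_size, label="rAI_sphere")
    x = rng.normal(0.0, 1.0, size=t)
    jitter = rng.normal(0.0, spec.seed_voxel_noise_sd, size=(rai.n_voxels, t))
    data[rai.values] = x + jitter

    # frontal search block with one planted causal voxel (bounds scale
    # with the grid; defaults give a 6 x 6 x 4 block on 24 x 24 x 18)
    x0, x1 = shape[0] // 8, max(shape[0] // 8 + 2, 3 * shape[0] // 8)
    y0, y1 = 7 * shape[1] // 12, max(7 * shape[1] // 12 + 2, 5 * shape[1] // 6)
    z0, z1 = 5 * shape[2] // 9, max(5 * shape[2] // 9 + 2, 7 * shape[2] // 9)
    block = np.zeros(shape, dtype=bool)
    block[x0:x1, y0:y1, z0:z1] = True
    lmfg = VoxelMask(block, label="lMFG")
    planted = ((x0 + x1) // 2, (y0 + y1) // 2, (z0 + z1) // 2)
    assert block[planted]
    eps = rng.normal(0.0, spec.noise_sd, size=t)
    y = np.empty(t)
    y[0] = eps[0]
    y[1:] = spec.coupling * x[:-1] + eps[1:]
    data[planted] = y

    # nuisance blocks: shared physiological drifts plus voxel noise
    wx, ny, nz = 5 * shape[0] // 12, shape[1] // 4, shape[2] // 3
    cx = 7 * shape[0] // 12
    wm_block = np.zeros(shape, dtype=bool)
    wm_block[wx:wx + 3, ny:ny + 3, nz:nz + 3] = True
    csf_block = np.zeros(shape, dtype=bool)
    csf_block[cx:cx + 3, ny:ny + 3, nz:nz + 3] = True
    wm_sig = rng.normal(0.0, 0.5, size=t)
    csf_sig = rng.normal(0.0, 0.5, size=t)
    data[wm_block] += wm_sig
    data[csf_block] += csf_sig

    affine = np.diag([*spec.voxel_size, 1.0])
    bold = BoldSeries(data, spec.voxel_size, spec.tr, affine=affine)

    # z-scored "components": winner covers the search block, decoys elsewhere
    def blob(mask: np.ndarray, level: float = 3.0) -> np.ndarray:
        m = np.where(mask, level, 0.0)
        return m + rng.normal(0.0, 0.2, size=shape)

    winner = blob(block)
    decoy_mask = np.zeros(shape, dtype=bool)
    decoy_mask[2 * shape[0] // 3:11 * shape[0] // 12, y0:y1, z0:z1] = True
    decoy = blob(decoy_mask)
    noise_comp = rng.normal(0.0, 1.0, size=shape)
    template = SpatialMap(np.where(block, 3.0, 0.0), affine)
    components = [SpatialMap(decoy, affine), SpatialMap(winner, affine),
                  SpatialMap(noise_comp, affine)]

    return VarBoldFixture(
        bold=bold,
        rai=rai,
        lmfg=lmfg,
        wm=VoxelMask(wm_block, label="WM", affine=affine),
        csf=VoxelMask(csf_block, label="CSF", affine=affine),
        components=components,
        template=template,
        true_target_voxel=planted,
        seed_series_truth=x,
    )


def make_head_fixture(
    kind: str = "sphere",
    radius: float | tuple[float, float, float] = 80.0,
    subdivisions: int = 4,
    center: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> HeadFixture:
    """Sphere or ellipsoid head mesh with analytic landmarks and normals.

    Landmark convention matches the head frame the planner expects:
    nasion on the +x surface point, left preauricular on +y, right on -y.
    For a sphere these lie on the equator, so the NLR origin is the
    sphere center.
    """
    center = np.asarray(center, dtype=float)
    if kind == "sphere":
        semiaxes = np.full(3, float(radius))
    elif kind == "ellipsoid":
        semiaxes = np.asarray(radius, dtype=float).reshape(3)
    else:
        raise ValueError(f"unknown head fixture kind {kind!r}")
    unit = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    vertices = np.asarray(unit.vertices) * semiaxes + center
    mesh = HeadModel(vertices, np.asarray(unit.faces))
    landmarks = LandmarkSet(
        nasion=center + [semiaxes[0], 0.0, 0.0],
        left_preauricular=center + [0.0, semiaxes[1], 0.0],
        right_preauricular=center + [0.0, -semiaxes[1], 0.0],
    )
    return HeadFixture(mesh=mesh, landmarks=landmarks, center=center, semiaxes=semiaxes)


def make_motion_trace(
    n_frames: int = 240,
    spike_frames: tuple[int, ...] = (),
    spike_sizes_mm: tuple[float, ...] = (),
    jitter_sd_mm: float = 0.02,
    jitter_sd_rad: float = 0.0002,
    random_seed: int = 0,
) -> MotionTrace:
    """Realignment parameters with small jitter and optional x-translation spikes.

    A spike of size s at frame k is a one-frame step in x translation, so
    the FD at frame k is s (plus jitter terms).
    """
    if len(spike_frames) != len(spike_sizes_mm):
        raise ValueError("spike_frames and spike_sizes_mm must have equal length")
    rng = np.random.default_rng(random_seed)
    steps = np.column_stack(
        [
            rng.normal(0.0, jitter_sd_mm, size=(n_frames, 3)),
            rng.normal(0.0, jitter_sd_rad, size=(n_frames, 3)),
        ]
    )
    steps[0] = 0.0
    params = np.cumsum(steps, axis=0)
    for frame, size in zip(spike_frames, spike_sizes_mm):
        params[frame:, 0] += size  # sustained step: one-frame displacement
    return MotionTrace(params)


def make_megapress(
    peaks: list[tuple[float, float, float]] | None = None,
    edited_on_only: list[tuple[float, float, float]] | None = None,
    n_on: int = 160,
    n_off: int = 160,
    n_points: int = 1024,
    dwell_time: float = 5e-4,
    spectrometer_frequency: float = 123.2,  # MHz, 3 T proton
    freq_jitter_hz: float = 0.0,
    phase_jitter_deg: float = 0.0,
    snr: float = 50.0,
    random_seed: int = 0,
) -> tuple[EditedSpectrumSet, dict]:
    """Interleaved ON/OFF MEGA-PRESS FIDs with known composition.

    ``peaks`` are (ppm, amplitude, linewidth Hz) Lorentzians present in
    every acquisition; ``edited_on_only`` resonances appear only in ON
    FIDs. Per-acquisition frequency/phase jitter is drawn i.i.d. normal;
    complex white noise is scaled so that the first time-domain sample of
    the summed signal over its SD equals ``snr``. Returns the set plus a
    ground-truth dict (per-FID jitters, noise SD, peak tables).
    """
    if peaks is None:
        peaks = [(3.2, 1.0, 6.0), (3.0, 1.2, 6.0), (2.0, 1.5, 6.0)]  # Cho, Cr, NAA
    if edited_on_only is None:
        edited_on_only = [(3.0, 0.3, 8.0)]  # edited GABA at 3 ppm
    rng = np.random.default_rng(random_seed)
    t = np.arange(n_points) * dwell_time

    def fid_for(table: list[tuple[float, float, float]]) -> np.ndarray:
        out = np.zeros(n_points, dtype=complex)
        for ppm, amp, lw_hz in table:
            f = (ppm - WATER_PPM) * spectrometer_frequency
            out += amp * np.exp(2j * np.pi * f * t) * np.exp(-np.pi * lw_hz * t)
        return out

    base_off = fid_for(peaks)
    base_on = base_off + fid_for(edited_on_only)
    noise_sd = abs(base_off[0]) / snr if snr > 0 else 0.0

    n_total = n_on + n_off
    labels = ["ON" if i % 2 == 0 else "OFF" for i in range(n_total)]
    # trim/extend the interleave to hit the exact per-label counts
    labels = (["ON"] * n_on + ["OFF"] * n_off) if labels.count("ON") != n_on else labels

    f_jit = rng.normal(0.0, freq_jitter_hz, size=n_total)
    p_jit = rng.normal(0.0, np.deg2rad(phase_jitter_deg), size=n_total)
    fids = np.empty((n_total, n_points), dtype=complex)
    for i, lab in enumerate(labels):
        base = base_on if lab == "ON" else base_off
        modulated = base * np.exp(1j * (2 * np.pi * f_jit[i] * t + p_jit[i]))
        noise = noise_sd * (
            rng.normal(size=n_points) + 1j * rng.normal(size=n_points)
        )
        fids[i] = modulated + noise

    water = 50.0 * np.exp(2j * np.pi * 0.0 * t) * np.exp(-np.pi * 8.0 * t)
    sset = EditedSpectrumSet(
        fids=fids,
        labels=labels,
        water_reference=water,
        dwell_time=dwell_time,
        spectrometer_frequency=spectrometer_frequency,
    )
    truth = {
        "frequency_jitter_hz": f_jit,
        "phase_jitter_deg": np.rad2deg(p_jit),
        "noise_sd": noise_sd,
        "peaks": peaks,
        "edited_on_only": edited_on_only,
    }
    return sset, truth
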