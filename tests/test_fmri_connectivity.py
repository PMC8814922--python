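"""Denoising, component selection, Granger mapping and target extraction."""

import numpy as np
import pytest
from scipy import ndimage

from brightpath.fmri_connectivity import (
    BoldSeries,
    NoSignificantTargetError,
    SpatialMap,
    VoxelMask,
    binarize_and_erode_mask,
    gca_zmap,
    granger_first_order,
    highpass,
    peak_cluster_target,
    project_point_to_mask,
    regress_nuisance,
    seed_series,
    select_component,
    sphere_mask,
)


def small_bold(data, tr=2.0, voxel_size=(3.0, 3.0, 3.0)):
    return BoldSeries(np.asarray(data, dtype=float), voxel_size, tr)


class TestBinarizeAndErode:
    def test_full_grid_loses_boundary_shell(self):
        prob = SpatialMap(np.ones((12, 12, 12)))
        mask = binarize_and_erode_mask(prob, threshold=0.98, radius_voxels=2)
        assert mask.values[2:-2, 2:-2, 2:-2].all()
        assert not mask.values[:2].any() and not mask.values[-2:].any()

    def test_subthreshold_map_is_empty(self):
        mask = binarize_and_erode_mask(SpatialMap(np.full((8, 8, 8), 0.5)))
        assert mask.n_voxels == 0

    def test_matches_neighborhood_scan_oracle(self, rng):
        """Erosion equals per-voxel min over the spherical neighborhood."""
        prob = rng.uniform(size=(10, 10, 10))
        radius = 2
        mask = binarize_and_erode_mask(SpatialMap(prob), 0.6, radius)
        binary = prob >= 0.6
        offsets = [
            (i, j, k)
            for i in range(-radius, radius + 1)
            for j in range(-radius, radius + 1)
            for k in range(-radius, radius + 1)
            if i * i + j * j + k * k <= radius * radius
        ]
        for x in range(10):
            for y in range(10):
                for z in range(10):
                    expected = all(
                        0 <= x + i < 10 and 0 <= y + j < 10 and 0 <= z + k < 10
                        and binary[x + i, y + j, z + k]
                        for i, j, k in offsets
                    )
                    assert mask.values[x, y, z] == expected

    def test_rejects_out_of_range_probabilities(self):
        with pytest.raises(ValueError):
            binarize_and_erode_mask(SpatialMap(np.full((4, 4, 4), 1.5)))


class TestRegressNuisance:
    @pytest.fixture()
    def masks(self):
        wm = np.zeros((4, 4, 4), dtype=bool)
        wm[0, 0, 0] = True
        csf = np.zeros((4, 4, 4), dtype=bool)
        csf[3, 3, 3] = True
        return VoxelMask(wm, "WM"), VoxelMask(csf, "CSF")

    def test_voxel_equal_to_regressor_zeroed(self, rng, masks):
        wm, csf = masks
        data = rng.normal(size=(4, 4, 4, 50))
        data[1, 1, 1] = data[0, 0, 0]  # copy of the WM series
        out = regress_nuisance(small_bold(data), wm, csf)
        assert np.abs(out.data[1, 1, 1]).max() < 1e-10

    def test_zero_regressors_demean_only(self, masks, rng):
        wm, csf = masks
        data = rng.normal(size=(4, 4, 4, 50))
        data[0, 0, 0] = 0.0
        data[3, 3, 3] = 0.0
        out = regress_nuisance(small_bold(data), wm, csf)
        expected = data - data.mean(axis=3, keepdims=True)
        assert out.data[1, 2, 3] == pytest.approx(expected[1, 2, 3], abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng, masks):
        wm, csf = masks
        data = rng.normal(size=(4, 4, 4, 60))
        bold = small_bold(data)
        out = regress_nuisance(bold, wm, csf)
        x = np.column_stack([np.ones(60), data[0, 0, 0], data[3, 3, 3]])
        xtx_inv = np.linalg.inv(x.T @ x)
        for voxel in [(1, 1, 1), (2, 0, 3), (3, 2, 1)]:
            y = data[voxel]
            beta = xtx_inv @ x.T @ y
            assert out.data[voxel] == pytest.approx(y - x @ beta, abs=1e-9)
            # residual orthogonal to both regressors
            assert abs(out.data[voxel] @ data[0, 0, 0]) < 1e-7 * np.abs(y).sum()

    def test_empty_mask_rejected(self, masks, rng):
        wm, _ = masks
        empty = VoxelMask(np.zeros((4, 4, 4), dtype=bool), "CSF")
        with pytest.raises(ValueError):
            regress_nuisance(small_bold(rng.normal(size=(4, 4, 4, 50))), wm, empty)


class TestHighpass:
    def make_series(self, signal):
        data = np.zeros((2, 2, 2, len(signal)))
        data[0, 0, 0] = signal
        return small_bold(data)

    def test_passband_sinusoid_preserved(self):
        t = np.arange(240) * 2.0
        sig = np.sin(2 * np.pi * 0.05 * t)
        out = highpass(self.make_series(sig), 0.01).data[0, 0, 0]
        assert np.abs(out).max() == pytest.approx(1.0, rel=0.05)
        # spectral amplitude at the tone within 5% (discrete Fourier oracle)
        amp_in = np.abs(np.fft.rfft(sig))
        amp_out = np.abs(np.fft.rfft(out))
        bin_idx = np.argmax(amp_in)
        assert amp_out[bin_idx] == pytest.approx(amp_in[bin_idx], rel=0.05)

    def test_constant_series_zeroed(self):
        out = highpass(self.make_series(np.full(100, 7.0)), 0.01)
        assert np.abs(out.data).max() < 1e-10

    def test_slow_drift_strongly_attenuated(self):
        t = np.arange(1000) * 2.0  # 4 full cycles of the drift
        sig = np.sin(2 * np.pi * 0.002 * t)
        out = highpass(self.make_series(sig), 0.01).data[0, 0, 0]
        assert np.abs(out).max() < 0.1 * np.abs(sig).max()

    def test_invalid_cutoffs(self):
        series = self.make_series(np.random.default_rng(0).normal(size=50))
        with pytest.raises(ValueError):
            highpass(series, 0.0)
        with pytest.raises(ValueError):
            highpass(series, 1.0)  # above Nyquist at TR 2 s


class TestSelectComponent:
    def make_maps(self, rng):
        shape = (10, 10, 8)
        template = np.zeros(shape)
        template[2:6, 2:6, 2:5] = 3.0
        noise = rng.normal(size=shape)
        return SpatialMap(template), [
            SpatialMap(template + rng.normal(0, 0.1, shape)),
            SpatialMap(-template + rng.normal(0, 0.1, shape)),
            SpatialMap(noise),
        ]

    def test_selects_template_copy(self, rng):
        template, comps = self.make_maps(rng)
        idx, winner = select_component(comps, template)
        assert idx == 0
        assert (winner.values >= 0).all()  # subthreshold values zeroed

    def test_single_candidate(self, rng):
        template, comps = self.make_maps(rng)
        idx, _ = select_component([comps[0]], template)
        assert idx == 0

    def test_matches_brute_force_scan(self, rng):
        """Winner equals exhaustive correlation over filtered candidates."""
        shape = (8, 8, 8)
        template = np.zeros(shape)
        template[1:4, 1:4, 1:4] = 2.5
        comps = [SpatialMap(rng.normal(1.0, 1.0, shape)) for _ in range(5)]
        idx, _ = select_component(comps, SpatialMap(template), z_threshold=1.96)
        corrs = []
        for comp in comps:
            filtered = np.where(comp.values >= 1.96, comp.values, 0.0)
            corrs.append(np.corrcoef(filtered.ravel(), template.ravel())[0, 1])
        assert idx == int(np.argmax(corrs))

    def test_invariant_to_positive_rescaling(self, rng):
        template, comps = self.make_maps(rng)
        idx0, _ = select_component(comps, template)
        scaled = [SpatialMap(c.values * s) for c, s in zip(comps, (1.5, 2.0, 4.0))]
        idx1, _ = select_component(scaled, template)
        assert idx0 == idx1

    def test_all_degenerate_raises(self):
        template = SpatialMap(np.random.default_rng(1).normal(size=(4, 4, 4)))
        flat = [SpatialMap(np.zeros((4, 4, 4)))]
        with pytest.raises(ValueError):
            select_component(flat, template)


class TestSeedSeries:
    def test_single_voxel_roi(self, rng):
        data = rng.normal(size=(3, 3, 3, 20))
        roi = np.zeros((3, 3, 3), dtype=bool)
        roi[1, 2, 0] = True
        assert seed_series(small_bold(data), VoxelMask(roi)) == pytest.approx(
            data[1, 2, 0])

    def test_opposite_series_cancel(self, rng):
        data = np.zeros((2, 2, 2, 30))
        s = rng.normal(size=30)
        data[0, 0, 0], data[1, 1, 1] = s, -s
        roi = np.zeros((2, 2, 2), dtype=bool)
        roi[0, 0, 0] = roi[1, 1, 1] = True
        assert np.abs(seed_series(small_bold(data), VoxelMask(roi))).max() < 1e-12

    def test_matches_explicit_summation(self, rng):
        data = rng.normal(size=(4, 4, 4, 25))
        roi = rng.uniform(size=(4, 4, 4)) > 0.6
        roi[0, 0, 0] = True
        expected = sum(data[tuple(v)] for v in np.argwhere(roi)) / roi.sum()
        assert seed_series(small_bold(data), VoxelMask(roi)) == pytest.approx(expected)

    def test_empty_roi_raises(self, rng):
        with pytest.raises(ValueError):
            seed_series(small_bold(rng.normal(size=(2, 2, 2, 20))),
                        VoxelMask(np.zeros((2, 2, 2), dtype=bool)))


def ols_granger_oracle(x, y):
    """Normal-equations oracle for the standardized first-order model."""
    xs = (x - x.mean()) / x.std()
    ys = (y - y.mean()) / y.std()
    design = np.column_stack([np.ones(len(x) - 1), ys[:-1], xs[:-1]])
    beta = np.linalg.solve(design.T @ design, design.T @ ys[1:])
    return beta[2]


class TestGrangerFirstOrder:
    def test_matches_ols_oracle_on_planted_coupling(self, rng):
        t = 240
        x = rng.normal(size=t)
        y = np.concatenate([[0.0], 0.8 * x[:-1]]) + rng.normal(0, 1.0, t)
        b = granger_first_order(x, y)
        assert b == pytest.approx(ols_granger_oracle(x, y), abs=1e-10)
        assert b > 0.3

    def test_independent_noise_is_unbiased(self, rng):
        bs = []
        for _ in range(1000):
            x = rng.normal(size=60)
            y = rng.normal(size=60)
            bs.append(granger_first_order(x, y))
        assert abs(np.mean(bs)) < 0.01

    def test_pure_autoregression_gives_vanishing_coefficient(self, rng):
        t = 10_000
        x = rng.normal(size=t)
        y = np.empty(t)
        y[0] = rng.normal()
        for i in range(1, t):
            y[i] = 0.6 * y[i - 1] + rng.normal()
        assert abs(granger_first_order(x, y)) < 0.05

    def test_asymmetry_under_directed_coupling(self, rng):
        """x->y coupling yields |b(x->y)| >> |b(y->x)| (median ratio > 3)."""
        ratios = []
        for _ in range(100):
            x = rng.normal(size=240)
            y = np.concatenate([[0.0], 0.5 * x[:-1]]) + rng.normal(0, 1.0, 240)
            fwd = abs(granger_first_order(x, y))
            rev = abs(granger_first_order(y, x))
            ratios.append(fwd / max(rev, 1e-12))
        assert np.median(ratios) > 3

    def test_degenerate_inputs_raise(self, rng):
        x = rng.normal(size=50)
        with pytest.raises(ValueError):
            granger_first_order(np.zeros(50), x)
        with pytest.raises(np.linalg.LinAlgError):
            granger_first_order(x, x.copy())
        with pytest.raises(ValueError):
            granger_first_order(x[:5], x[:5] * 2)


class TestGcaZmap:
    def make_inputs(self, rng, n_mask=40, t=240, coupling=0.5):
        shape = (6, 6, 6)
        data = rng.normal(size=(*shape, t))
        mask = np.zeros(shape, dtype=bool)
        flat = rng.choice(np.prod(shape), size=n_mask, replace=False)
        mask[np.unravel_index(flat, shape)] = True
        seed = rng.normal(size=t)
        planted = tuple(np.argwhere(mask)[n_mask // 2])
        data[planted] = np.concatenate([[0.0], coupling * seed[:-1]]) + rng.normal(
            0, 1.0, t)
        return small_bold(data), seed, VoxelMask(mask), planted

    def test_standardization_identity(self, rng):
        bold, seed, mask, _ = self.make_inputs(rng)
        zmap = gca_zmap(bold, seed, mask)
        in_mask = zmap.values[mask.values]
        assert in_mask.mean() == pytest.approx(0.0, abs=1e-12)
        assert in_mask.std() == pytest.approx(1.0, abs=1e-12)
        assert (zmap.values[~mask.values] == 0).all()

    def test_batched_coefficients_match_scalar_path(self, rng):
        bold, seed, mask, _ = self.make_inputs(rng, n_mask=15)
        zmap = gca_zmap(bold, seed, mask)
        bs = np.array([
            granger_first_order(seed, bold.data[tuple(v)])
            for v in np.argwhere(mask.values)
        ])
        expected_z = (bs - bs.mean()) / bs.std()
        assert zmap.values[mask.values] == pytest.approx(expected_z, abs=1e-9)

    def test_planted_voxel_attains_maximum(self, rng):
        hits = 0
        for _ in range(20):
            bold, seed, mask, planted = self.make_inputs(rng)
            zmap = gca_zmap(bold, seed, mask)
            peak = np.unravel_index(np.argmax(np.where(mask.values, zmap.values,
                                                       -np.inf)), zmap.values.shape)
            hits += peak == planted
        assert hits >= 19

    def test_identical_series_raise(self):
        data = np.ones((3, 3, 3, 30)) * np.arange(30)
        mask = np.ones((3, 3, 3), dtype=bool)
        with pytest.raises(ValueError):
            gca_zmap(small_bold(data), np.arange(30.0), VoxelMask(mask))


class TestPeakClusterTarget:
    def test_single_suprathreshold_voxel(self):
        z = np.zeros((5, 5, 5))
        z[2, 3, 1] = 4.0
        mask = VoxelMask(np.ones((5, 5, 5), dtype=bool))
        target = peak_cluster_target(SpatialMap(z), mask)
        assert target.voxel_index == (2, 3, 1)
        assert target.peak_z == pytest.approx(4.0)

    def test_higher_cluster_wins(self):
        z = np.zeros((8, 8, 8))
        z[1, 1, 1] = z[1, 1, 2] = 3.0
        z[6, 6, 6] = 4.0
        z[6, 6, 5] = 3.5
        mask = VoxelMask(np.ones((8, 8, 8), dtype=bool))
        assert peak_cluster_target(SpatialMap(z), mask).voxel_index == (6, 6, 6)

    def test_matches_exhaustive_argmax(self, rng):
        for _ in range(10):
            z = rng.normal(size=(6, 6, 6))
            mask = rng.uniform(size=(6, 6, 6)) > 0.3
            supra = (z > 1.96) & mask
            if not supra.any():
                continue
            expected = np.unravel_index(
                np.argmax(np.where(supra, z, -np.inf)), z.shape)
            got = peak_cluster_target(SpatialMap(z), VoxelMask(mask)).voxel_index
            assert got == expected

    def test_peak_lies_in_a_26_connected_cluster(self, rng):
        z = rng.normal(size=(6, 6, 6)) + 1.0
        mask = VoxelMask(np.ones((6, 6, 6), dtype=bool))
        target = peak_cluster_target(SpatialMap(z), mask)
        labels, _ = ndimage.label(z > 1.96, structure=np.ones((3, 3, 3)))
        assert labels[target.voxel_index] > 0

    def test_no_suprathreshold_voxel_raises(self):
        z = np.zeros((4, 4, 4))
        with pytest.raises(NoSignificantTargetError):
            peak_cluster_target(SpatialMap(z), VoxelMask(np.ones((4, 4, 4), bool)))


class TestProjectPointToMask:
    def test_point_inside_mask(self):
        mask = VoxelMask(np.ones((10, 10, 10), dtype=bool))
        target = project_point_to_mask((9.0, 6.0, 3.0), mask, voxel_size=(3, 3, 3))
        assert target.voxel_index == (3, 2, 1)
        assert target.world_mm == pytest.approx((9.0, 6.0, 3.0))

    def test_single_voxel_mask(self):
        values = np.zeros((4, 4, 4), dtype=bool)
        values[0, 0, 0] = True
        target = project_point_to_mask((5.0, 5.0, 5.0), VoxelMask(values),
                                       voxel_size=(1, 1, 1))
        assert target.voxel_index == (0, 0, 0)

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(10):
            values = rng.uniform(size=(7, 7, 7)) > 0.5
            values[3, 3, 3] = True
            point = rng.uniform(-5, 25, size=3)
            vs = (2.0, 2.5, 3.0)
            best, best_d = None, np.inf
            for v in np.argwhere(values):
                d = np.linalg.norm(v * vs - point)
                if d < best_d - 1e-12:
                    best, best_d = tuple(v), d
            got = project_point_to_mask(tuple(point), VoxelMask(values), voxel_size=vs)
            assert got.voxel_index == best

    def test_respects_affine_offset(self):
        values = np.ones((5, 5, 5), dtype=bool)
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        affine[:3, 3] = [-4.0, -4.0, -4.0]
        target = project_point_to_mask((0.0, 0.0, 0.0), VoxelMask(values),
                                       affine=affine)
        assert target.voxel_index == (2, 2, 2)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            project_point_to_mask((0, 0, 0), VoxelMask(np.zeros((3, 3, 3), bool)),
                                  voxel_size=(1, 1, 1))


class TestSphereMask:
    def test_radius_six_mm_at_three_mm_voxels(self):
        mask = sphere_mask((9, 9, 9), (4, 4, 4), 6.0, (3.0, 3.0, 3.0))
        center_distances = np.linalg.norm(
            (np.argwhere(mask.values) - [4, 4, 4]) * 3.0, axis=1)
        assert (center_distances <= 6.0).all()
        assert mask.values[4, 4, 4]
        assert mask.n_voxels == 33  # 6 mm ball on a 3 mm grid
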