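"""Acquisition operator: slice profile, frequency filter, adjoint, noise."""

import math

import numpy as np
import pytest

from srrmri.forward_model import (
    AcquisitionSpec,
    NoiseModel,
    add_noise,
    adjoint_forward,
    apply_forward,
    build_filter,
    profile_sigma,
    simulate_acquisitions,
)
from srrmri.transforms import RigidTransform
from srrmri.volumes import Volume, VoxelGrid


@pytest.fixture
def spec24(small_grid):
    return AcquisitionSpec.for_hr_grid(small_grid, "z", 2.0)


class TestProfileSigma:
    def test_two_mm_slice(self):
        assert profile_sigma(2.0) == pytest.approx(0.8493, abs=5e-5)

    def test_fwhm_definition(self):
        assert profile_sigma(2.0 * math.sqrt(2.0 * math.log(2.0))) == pytest.approx(1.0)

    def test_linear_scaling(self):
        assert profile_sigma(4.0) == pytest.approx(2 * profile_sigma(2.0))

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            profile_sigma(0.0)


class TestAcquisitionSpec:
    def test_grid_arithmetic_96_cube(self):
        g = VoxelGrid((96, 96, 96), (0.5, 0.5, 0.5))
        spec = AcquisitionSpec.for_hr_grid(g, "y", 2.0)
        assert spec.n_slices == 24  # 96 * 0.5 / 2
        assert spec.lr_grid.shape == (96, 24, 96)
        assert spec.lr_grid.spacing == (0.5, 2.0, 0.5)

    def test_isotropic_stack_rejected(self, small_grid):
        with pytest.raises(ValueError, match="anisotropic"):
            AcquisitionSpec("z", 0.25, (0.5, 0.5), 12, small_grid)

    def test_too_many_slices_rejected(self, small_grid):
        with pytest.raises(ValueError):
            AcquisitionSpec("z", 2.0, (0.5, 0.5), 48, small_grid)


class TestFrequencyFilter:
    def test_dc_gain_is_exactly_one(self, spec24):
        filt = build_filter(spec24)
        n = spec24.hr_grid.shape[2]
        assert filt.transfer[n // 2] == 1.0

    def test_band_edge_attenuation_matches_closed_form(self, spec24):
        # at f = 1/(2 * thickness) the Gaussian transfer is exp(-pi^2/(16 ln 2))
        filt = build_filter(spec24)
        n = spec24.hr_grid.shape[2]
        d = spec24.hr_grid.spacing[2]
        f = np.fft.fftshift(np.fft.fftfreq(n, d=d))
        f_edge = 1.0 / (2.0 * spec24.slice_thickness)
        idx = int(np.argmin(np.abs(f - f_edge)))
        assert f[idx] == pytest.approx(f_edge)
        assert filt.transfer[idx] == pytest.approx(math.exp(-math.pi**2 / (16 * math.log(2))), rel=1e-6)
        assert filt.transfer[idx] == pytest.approx(0.411, abs=5e-4)

    def test_keep_band_width_and_centering(self, spec24):
        filt = build_filter(spec24)
        assert filt.n_keep == spec24.n_slices
        n = spec24.hr_grid.shape[2]
        start, stop = filt.keep_band
        assert start <= n // 2 < stop

    def test_transfer_symmetric_about_dc(self, spec24):
        t = build_filter(spec24).transfer
        n = t.size
        # exclude the unpaired negative-Nyquist sample of an even-length grid
        np.testing.assert_allclose(t[1:], t[1:][::-1], atol=1e-12)


class TestApplyForward:
    def test_constant_volume_preserved(self, small_grid, spec24):
        x = Volume(small_grid, np.full(small_grid.shape, 5.0))
        y = apply_forward(x, None, spec24)
        assert y.data.shape == (24, 24, 6)
        np.testing.assert_allclose(y.data, 5.0, atol=1e-8)

    def test_inband_sinusoid_attenuated_analytically(self, small_grid, spec24):
        d = small_grid.spacing[2]
        f = 2.0 / (small_grid.shape[2] * d)  # 2 cycles across the FoV, inside band
        z_hr = np.arange(small_grid.shape[2]) * d
        x = Volume(small_grid, np.broadcast_to(np.cos(2 * np.pi * f * z_hr), small_grid.shape).copy())
        y = apply_forward(x, None, spec24)
        sigma = profile_sigma(spec24.slice_thickness)
        att = math.exp(-2 * math.pi**2 * sigma**2 * f**2)
        z_lr = np.arange(spec24.n_slices) * spec24.lr_grid.spacing[2]
        np.testing.assert_allclose(y.data[0, 0, :], att * np.cos(2 * np.pi * f * z_lr), atol=1e-6)

    def test_out_of_band_sinusoid_vanishes(self, small_grid, spec24):
        d = small_grid.spacing[2]
        f = 8.0 / (small_grid.shape[2] * d)  # above the 6-sample keep band
        z = np.arange(small_grid.shape[2]) * d
        x = Volume(small_grid, np.broadcast_to(np.cos(2 * np.pi * f * z), small_grid.shape).copy())
        y = apply_forward(x, None, spec24)
        np.testing.assert_allclose(y.data, 0.0, atol=1e-8)

    def test_linearity(self, small_grid, spec24, rng):
        x1 = Volume(small_grid, rng.standard_normal(small_grid.shape))
        x2 = Volume(small_grid, rng.standard_normal(small_grid.shape))
        lhs = apply_forward(Volume(small_grid, 2.0 * x1.data - 3.0 * x2.data), None, spec24)
        rhs = 2.0 * apply_forward(x1, None, spec24).data - 3.0 * apply_forward(x2, None, spec24).data
        np.testing.assert_allclose(lhs.data, rhs, atol=1e-8)

    def test_energy_contraction(self, small_grid, spec24, rng):
        x = Volume(small_grid, rng.standard_normal(small_grid.shape))
        y = apply_forward(x, None, spec24)
        assert np.linalg.norm(y.data) <= np.linalg.norm(x.data)

    def test_wrong_grid_rejected(self, spec24):
        g = VoxelGrid((12, 12, 12), (1, 1, 1))
        with pytest.raises(ValueError):
            apply_forward(Volume(g, np.zeros(g.shape)), None, spec24)


class TestAdjoint:
    def test_weighted_inner_product_identity(self, small_grid, spec24, rng):
        filt = build_filter(spec24)
        w = spec24.hr_grid.shape[2] / spec24.n_slices  # LR/HR voxel volume ratio
        for _ in range(10):
            x = Volume(small_grid, rng.standard_normal(small_grid.shape))
            y = Volume(spec24.lr_grid, rng.standard_normal(spec24.lr_grid.shape))
            lhs = w * np.sum(apply_forward(x, None, spec24, filt).data * y.data)
            rhs = np.sum(x.data * adjoint_forward(y, None, spec24, filt).data)
            rel = abs(lhs - rhs) / (np.linalg.norm(x.data) * np.linalg.norm(y.data))
            assert rel < 1e-6

    def test_plain_l2_inner_product_identity(self, small_grid, spec24, rng):
        x = Volume(small_grid, rng.standard_normal(small_grid.shape))
        y = Volume(spec24.lr_grid, rng.standard_normal(spec24.lr_grid.shape))
        lhs = np.sum(apply_forward(x, None, spec24).data * y.data)
        rhs = np.sum(x.data * adjoint_forward(y, None, spec24, voxel_weighted=False).data)
        assert abs(lhs - rhs) / (np.linalg.norm(x.data) * np.linalg.norm(y.data)) < 1e-6

    def test_adjoint_of_zero_is_zero(self, spec24):
        y = Volume(spec24.lr_grid, np.zeros(spec24.lr_grid.shape))
        assert np.all(adjoint_forward(y, None, spec24).data == 0)

    def test_constant_preserved_both_directions(self, small_grid, spec24):
        c = 3.5
        y = apply_forward(Volume(small_grid, np.full(small_grid.shape, c)), None, spec24)
        np.testing.assert_allclose(y.data, c, atol=1e-8)
        back = adjoint_forward(y, None, spec24, voxel_weighted=True)
        np.testing.assert_allclose(back.data, c, atol=1e-8)

    def test_identity_configuration_round_trips(self, small_grid, rng):
        # full-band spec with no blur: the operator degenerates to identity
        spec = AcquisitionSpec("z", 0.5, (0.5, 0.5), 24, small_grid)
        filt = build_filter(spec)
        object.__setattr__(filt, "transfer", np.ones_like(filt.transfer))
        x = Volume(small_grid, rng.standard_normal(small_grid.shape))
        y = apply_forward(x, None, spec, filt)
        np.testing.assert_allclose(y.data, x.data, atol=1e-10)
        np.testing.assert_allclose(adjoint_forward(y, None, spec, filt).data, x.data, atol=1e-10)


class TestNoise:
    def test_zero_sd_is_identity(self, small_volume):
        out = add_noise(small_volume, NoiseModel(0.0, 1))
        np.testing.assert_array_equal(out.data, small_volume.data)

    def test_sample_sd_matches_model(self):
        g = VoxelGrid((50, 50, 40), (1, 1, 1))
        y = Volume(g, np.zeros(g.shape))
        out = add_noise(y, NoiseModel(7.0, 5))
        assert out.data.std() == pytest.approx(7.0, rel=0.02)

    def test_deterministic_under_seed(self, small_volume):
        a = add_noise(small_volume, NoiseModel(2.0, 11))
        b = add_noise(small_volume, NoiseModel(2.0, 11))
        np.testing.assert_array_equal(a.data, b.data)


class TestSimulateAcquisitions:
    def test_three_orthogonal_stacks_shapes(self, phantom48):
        _, image, _ = phantom48
        specs = [AcquisitionSpec.for_hr_grid(image.grid, a, 2.0) for a in "xyz"]
        scans = simulate_acquisitions(image, specs, None, NoiseModel(0.0, 0))
        shapes = [s.data.shape for s in scans]
        assert shapes == [(12, 48, 48), (48, 12, 48), (48, 48, 12)]

    def test_single_scan_configuration(self, phantom48):
        _, image, _ = phantom48
        spec = AcquisitionSpec.for_hr_grid(image.grid, "z", 2.0)
        scans = simulate_acquisitions(image, [spec], None, NoiseModel(0.0, 0))
        assert len(scans) == 1

    def test_length_mismatch_rejected(self, phantom48):
        _, image, _ = phantom48
        spec = AcquisitionSpec.for_hr_grid(image.grid, "z", 2.0)
        with pytest.raises(ValueError):
            simulate_acquisitions(image, [spec], [RigidTransform(), RigidTransform()])

    def test_noiseless_adjoint_average_is_low_passed_truth(self, phantom48):
        # composing each scan's weighted adjoint and averaging applies
        # transfer^2 truncated per axis: a smooth approximation of the truth
        _, image, _ = phantom48
        specs = [AcquisitionSpec.for_hr_grid(image.grid, a, 2.0) for a in "xyz"]
        scans = simulate_acquisitions(image, specs, None, NoiseModel(0.0, 0))
        ups = [adjoint_forward(y, None, sp).data for y, sp in zip(scans, specs)]
        avg = np.mean(ups, axis=0)
        assert np.corrcoef(avg.ravel(), image.data.ravel())[0, 1] > 0.9
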