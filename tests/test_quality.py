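"""Quality metrics: GMM fitting, PVE estimation, noise, SNR/CNR, PSNR/SSIM."""

import math

import numpy as np
import pytest

from srrmri.quality import (
    GMMFit,
    cnr_db,
    default_background_region,
    estimate_noise_sd,
    estimate_pve,
    fit_gmm3,
    psnr,
    pure_tissue_interval,
    snr_db,
    ssim,
)
from srrmri.volumes import RegionMask, Volume, VoxelGrid

ERF_COVERAGE = math.erf(math.sqrt(math.log(2)))  # pure-Gaussian FWHM-interval mass


@pytest.fixture(scope="module")
def mixture_sample():
    rng = np.random.default_rng(21)
    return np.concatenate(
        [
            rng.normal(100.0, 10.0, 30000),
            rng.normal(200.0, 10.0, 40000),
            rng.normal(300.0, 10.0, 30000),
        ]
    )


@pytest.fixture(scope="module")
def mixture_fit(mixture_sample):
    return fit_gmm3(mixture_sample, seed=0)


class TestFitGmm3:
    def test_recovers_means_and_weights(self, mixture_fit):
        np.testing.assert_allclose(mixture_fit.means, (100, 200, 300), atol=2.0)
        np.testing.assert_allclose(mixture_fit.weights, (0.3, 0.4, 0.3), atol=0.02)

    def test_near_separable_clusters_recover_weights_tightly(self):
        rng = np.random.default_rng(4)
        x = np.concatenate(
            [rng.normal(0, 0.1, 2000), rng.normal(50, 0.1, 5000), rng.normal(100, 0.1, 3000)]
        )
        fit = fit_gmm3(x, seed=0)
        np.testing.assert_allclose(fit.weights, (0.2, 0.5, 0.3), atol=0.01)

    def test_deterministic_given_seed(self, mixture_sample):
        f1 = fit_gmm3(mixture_sample, seed=0)
        f2 = fit_gmm3(mixture_sample, seed=0)
        assert f1.means == f2.means and f1.weights == f2.weights

    def test_requires_enough_samples(self):
        with pytest.raises(ValueError, match="300"):
            fit_gmm3(np.zeros(100) + np.arange(100))

    def test_t1_vs_t2_assignment(self, mixture_sample):
        assert fit_gmm3(mixture_sample, contrast="t2").assignment == ("GM", "WM", "CSF")
        assert fit_gmm3(mixture_sample, contrast="t1").assignment == ("CSF", "GM", "WM")


class TestPureTissueInterval:
    def test_unit_gaussian_interval(self):
        lo, hi = pure_tissue_interval(0.0, 1.0)
        assert lo == pytest.approx(-1.1774, abs=5e-5)
        assert hi == pytest.approx(1.1774, abs=5e-5)

    def test_width_scales_with_sigma(self):
        lo1, hi1 = pure_tissue_interval(0.0, 1.0)
        lo3, hi3 = pure_tissue_interval(0.0, 3.0)
        assert hi3 - lo3 == pytest.approx(3 * (hi1 - lo1))

    def test_coverage_is_erf_sqrt_ln2(self):
        rng = np.random.default_rng(8)
        draws = rng.normal(5.0, 2.5, 400000)
        lo, hi = pure_tissue_interval(5.0, 2.5)
        cover = ((draws >= lo) & (draws <= hi)).mean()
        assert cover == pytest.approx(ERF_COVERAGE, abs=0.01)
        assert ERF_COVERAGE == pytest.approx(0.7610, abs=5e-4)


class TestEstimatePve:
    def grid_volume(self, vals):
        n = round(len(vals) ** (1 / 3))
        g = VoxelGrid((n, n, n), (1, 1, 1))
        v = Volume(g, np.asarray(vals[: n**3]).reshape(n, n, n))
        return v, RegionMask(g, np.ones(g.shape, dtype=bool))

    def test_all_pure_voxels_give_zero(self):
        fit = GMMFit((100.0, 200.0, 300.0), (10.0, 10.0, 10.0), (1 / 3,) * 3, 0.0)
        vals = np.full(27**3, 200.0)
        v, region = self.grid_volume(vals)
        assert estimate_pve(v, region, fit) == 0.0

    def test_pure_gaussian_classes_hit_analytic_floor(self, mixture_sample, mixture_fit):
        # well-separated pure classes: PVE floor = 100 * (1 - erf(sqrt(ln 2)))
        rng = np.random.default_rng(31)
        vals = rng.permutation(mixture_sample)
        v, region = self.grid_volume(vals)
        pve = estimate_pve(v, region, mixture_fit)
        assert pve == pytest.approx(100 * (1 - ERF_COVERAGE), abs=1.0)

    def test_monotone_in_injected_mixed_voxels(self, mixture_sample, mixture_fit):
        rng = np.random.default_rng(32)
        base = rng.permutation(mixture_sample)
        pves = []
        for q in (0.0, 0.1, 0.2, 0.4):
            vals = base.copy()
            k = int(q * len(vals))
            vals[:k] = 150.0  # midway between components: never pure
            v, region = self.grid_volume(vals)
            pves.append(estimate_pve(v, region, mixture_fit))
        assert all(b > a for a, b in zip(pves, pves[1:]))

    def test_empty_region_rejected(self, mixture_fit):
        g = VoxelGrid((8, 8, 8), (1, 1, 1))
        v = Volume(g, np.zeros(g.shape))
        with pytest.raises(ValueError):
            estimate_pve(v, RegionMask(g, np.zeros(g.shape, dtype=bool)), mixture_fit)


class TestNoiseSd:
    def test_constant_background_gives_zero(self):
        g = VoxelGrid((10, 10, 10), (1, 1, 1))
        v = Volume(g, np.full(g.shape, 3.0))
        assert estimate_noise_sd(v, RegionMask(g, np.ones(g.shape, bool))) == 0.0

    def test_gaussian_background_recovered(self):
        rng = np.random.default_rng(12)
        g = VoxelGrid((22, 22, 22), (1, 1, 1))
        v = Volume(g, rng.normal(0, 10.0, g.shape))
        sd = estimate_noise_sd(v, RegionMask(g, np.ones(g.shape, bool)))
        assert sd == pytest.approx(10.0, abs=0.3)

    def test_scales_with_intensity(self, rng):
        g = VoxelGrid((16, 16, 16), (1, 1, 1))
        v = Volume(g, rng.normal(0, 2.0, g.shape))
        m = RegionMask(g, np.ones(g.shape, bool))
        assert estimate_noise_sd(Volume(g, -3.0 * v.data), m) == pytest.approx(
            3.0 * estimate_noise_sd(v, m)
        )


class TestSnrCnr:
    FIT = GMMFit((100.0, 200.0, 300.0), (10.0, 10.0, 10.0), (0.3, 0.4, 0.3), 0.0)

    def test_snr_hand_arithmetic(self):
        # equal component sds make peak and mixing weights proportional
        assert snr_db(self.FIT, 10.0, "peak") == pytest.approx(10 * math.log10(20), abs=1e-9)
        assert snr_db(self.FIT, 10.0, "mixing") == pytest.approx(13.0103, abs=5e-4)

    def test_snr_collapses_for_equal_means(self):
        fit = GMMFit((200.0, 200.0, 200.0), (5.0, 10.0, 20.0), (0.2, 0.3, 0.5), 0.0)
        assert snr_db(fit, 10.0) == pytest.approx(10 * math.log10(20))

    def test_halving_noise_adds_3db(self):
        assert snr_db(self.FIT, 5.0) - snr_db(self.FIT, 10.0) == pytest.approx(
            10 * math.log10(2), abs=1e-9
        )

    def test_cnr_pairs(self):
        c_cg, c_cw, c_gw = cnr_db(self.FIT, 10.0)
        # T2 assignment: ascending means are GM, WM, CSF
        assert c_cg == pytest.approx(10 * math.log10(20))  # |300-100|/10
        assert c_cw == pytest.approx(10.0)  # |300-200|/10
        assert c_gw == pytest.approx(10.0)  # |200-100|/10

    def test_cnr_zero_db_when_difference_equals_noise(self):
        fit = GMMFit((100.0, 200.0, 300.0), (10.0,) * 3, (1 / 3,) * 3, 0.0)
        assert cnr_db(fit, 100.0)[2] == pytest.approx(0.0)

    def test_identical_means_undefined(self):
        fit = GMMFit((100.0, 100.0, 300.0), (10.0,) * 3, (1 / 3,) * 3, 0.0)
        c_cg, c_cw, c_gw = cnr_db(fit, 10.0)
        assert math.isnan(c_gw)  # GM and WM coincide under T2 assignment

    def test_nonpositive_noise_rejected(self):
        with pytest.raises(ValueError):
            snr_db(self.FIT, 0.0)
        with pytest.raises(ValueError):
            cnr_db(self.FIT, -1.0)


class TestPsnrSsim:
    def test_ssim_of_identical_volumes_is_one(self, phantom48):
        _, image, _ = phantom48
        assert ssim(image, image) == 1.0

    def test_psnr_closed_form_for_constant_error(self, phantom48):
        _, image, _ = phantom48
        c = 2.0
        shifted = Volume(image.grid, image.data + c)
        peak = image.data.max()
        assert psnr(shifted, image) == pytest.approx(20 * math.log10(peak / c), rel=1e-9)

    def test_ssim_decreases_with_noise(self, phantom48):
        _, image, _ = phantom48
        rng = np.random.default_rng(3)
        noise = rng.standard_normal(image.data.shape)
        vals = [ssim(Volume(image.grid, image.data + sd * noise), image) for sd in (1, 5, 10)]
        assert vals[0] > vals[1] > vals[2]

    def test_grid_mismatch_rejected(self, phantom48):
        _, image, _ = phantom48
        g = VoxelGrid((8, 8, 8), (1, 1, 1))
        with pytest.raises(ValueError):
            psnr(Volume(g, np.zeros(g.shape)), image)


def test_default_background_region_corners():
    g = VoxelGrid((20, 20, 20), (1, 1, 1))
    v = Volume(g, np.zeros(g.shape))
    m = default_background_region(v)
    assert m.selected[0, 0, 0] and m.selected[-1, -1, -1]
    assert not m.selected[10, 10, 10]
    assert m.count == 8 * 2**3
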