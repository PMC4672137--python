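import numpy as np
import pytest
from scipy import ndimage

import swarmcut as sc
from swarmcut.enhancement import (
    EnhancementParams,
    GlobalAppearanceModel,
    LBPParams,
    certainty_field,
    enhanced_image,
    global_model,
    lbp_map,
    local_profiles,
    w1_distance,
)


class TestLBP:
    def test_constant_slice_is_code_zero(self):
        assert np.all(lbp_map(np.full((8, 8), 50.0)) == 0)

    def test_center_below_all_neighbours_sets_all_bits(self):
        img = np.full((9, 9), 100.0)
        img[4, 4] = 0.0
        assert lbp_map(img)[4, 4] == 2**6 - 1

    def test_single_neighbour_sets_single_bit(self):
        # only the bilinear sample at angle index t=2 (120 deg) exceeds the
        # centre by more than zeta; its support pixels are (1,1) and (1,2)
        img = np.zeros((5, 5))
        img[1, 1] = img[1, 2] = 2.0
        assert lbp_map(img, LBPParams(zeta=1.6))[2, 2] == 4

    def test_codes_bounded(self):
        rng = np.random.default_rng(0)
        codes = lbp_map(rng.normal(size=(16, 16)) * 100)
        assert codes.min() >= 0 and codes.max() <= 63

    def test_param_validation(self):
        with pytest.raises(ValueError):
            LBPParams(m=2)
        with pytest.raises(ValueError):
            LBPParams(zeta=-1.0)


class TestLocalProfiles:
    def test_constant_grid_degenerate_histogram(self):
        edges = np.linspace(0, 10, 6)
        prof = local_profiles(np.full((6, 6), 3.0), edges, window=3)
        assert prof.shape == (6, 6, 5)
        np.testing.assert_allclose(prof.sum(-1), 1.0)
        assert np.all(prof[..., 1] == 1.0)

    def test_integral_histogram_matches_naive(self):
        rng = np.random.default_rng(5)
        feat = rng.uniform(0, 10, size=(16, 16))
        edges = np.linspace(0, 10, 9)
        window = 5
        prof = local_profiles(feat, edges, window)
        h = window // 2
        for r, c in [(0, 0), (3, 7), (8, 8), (15, 15), (2, 14)]:
            patch = feat[max(0, r - h) : r + h + 1, max(0, c - h) : c + h + 1]
            naive, _ = np.histogram(patch, bins=edges)
            np.testing.assert_allclose(prof[r, c], naive / naive.sum(), atol=1e-12)

    def test_whole_slice_window_gives_identical_profiles(self):
        rng = np.random.default_rng(2)
        feat = rng.uniform(0, 1, size=(8, 8))
        prof = local_profiles(feat, np.linspace(0, 1, 5), window=17)
        assert np.abs(prof - prof[0, 0]).max() < 1e-12


class TestW1:
    edges = np.arange(11.0)

    def _point(self, b):
        p = np.zeros(10)
        p[b] = 1.0
        return p

    def test_identity(self):
        p = self._point(3)
        assert w1_distance(p, p, self.edges) == 0.0

    def test_point_masses_closed_form(self):
        assert w1_distance(self._point(2), self._point(7), self.edges) == pytest.approx(5.0)

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            p, q, r = rng.dirichlet(np.ones(10), size=3)
            dpq = w1_distance(p, q, self.edges)
            assert dpq == pytest.approx(w1_distance(q, p, self.edges))
            assert dpq >= 0.0
            assert dpq <= w1_distance(p, r, self.edges) + w1_distance(r, q, self.edges) + 1e-12

    def test_mismatched_bins_rejected(self):
        with pytest.raises(ValueError):
            w1_distance(np.ones(5) / 5, np.ones(4) / 4, self.edges)


class TestGlobalModel:
    edges = np.arange(11.0)

    def test_identical_profiles_floor_variance(self):
        prof = np.tile(np.full(10, 0.1), (4, 4, 1))
        model = global_model(prof, np.ones((4, 4), bool), self.edges, sigma_floor=1e-3)
        np.testing.assert_allclose(model.mean_profile, 0.1)
        assert model.sigma_sq == 1e-3

    def test_two_point_masses(self):
        prof = np.zeros((2, 1, 10))
        prof[0, 0, 2] = 1.0
        prof[1, 0, 7] = 1.0
        model = global_model(prof, np.ones((2, 1), bool), self.edges)
        assert model.mean_profile[2] == pytest.approx(0.5)
        assert model.mean_profile[7] == pytest.approx(0.5)
        # each point profile sits at W1 = |a-b|/2 from the mean; sigma^2 is the
        # mean squared deviation
        assert model.sigma_sq == pytest.approx((5.0 / 2.0) ** 2)

    def test_empty_seed_mask_rejected(self):
        with pytest.raises(ValueError):
            global_model(np.zeros((2, 2, 10)), np.zeros((2, 2), bool), self.edges)


class TestCertainty:
    def test_matching_window_scores_zero(self):
        edges = np.arange(11.0)
        prof = np.tile(np.full(10, 0.1), (3, 3, 1))
        model = global_model(prof, np.ones((3, 3), bool), edges)
        np.testing.assert_allclose(certainty_field(prof, model), 0.0, atol=1e-9)

    def test_doubling_sigma_quarters_certainty(self):
        edges = np.arange(11.0)
        prof = np.zeros((1, 1, 10))
        prof[0, 0, 5] = 1.0
        m1 = GlobalAppearanceModel(np.full(10, 0.1), 1.0, edges)
        m2 = GlobalAppearanceModel(np.full(10, 0.1), 4.0, edges)  # sigma doubled
        np.testing.assert_allclose(certainty_field(prof, m1), 4 * certainty_field(prof, m2))


class TestEnhancedImage:
    def test_uniform_volume_is_flat_zero(self):
        vol = sc.CTVolume(np.full((3, 12, 12), 90.0))
        obj = np.zeros((3, 12, 12), bool)
        obj[1, 5:8, 5:8] = True
        bkg = np.zeros((3, 12, 12), bool)
        bkg[0, 0, 0] = True
        enh = enhanced_image(vol, sc.SeedSet(obj, bkg))
        np.testing.assert_allclose(enh, 0.0)

    def test_output_range(self, noisy_phantom):
        vol, _, seeds = noisy_phantom
        enh = enhanced_image(vol, seeds)
        assert enh.min() >= 0.0 and enh.max() <= 1.0

    def test_boundary_strip_more_certain_than_interior(self, noisy_phantom):
        vol, truth, seeds = noisy_phantom
        enh = enhanced_image(vol, seeds)
        z = vol.shape[0] // 2
        tr = truth[z]
        contour = tr & ~ndimage.binary_erosion(tr)
        strip = ndimage.binary_dilation(contour, iterations=2)
        interior = ndimage.binary_erosion(tr, iterations=4)
        assert enh[z][strip].mean() > enh[z][interior].mean()

    def test_offset_invariance_with_shifted_bins(self, clean_phantom):
        vol, _, seeds = clean_phantom
        params = EnhancementParams()
        edges = np.linspace(-100.0, 400.0, params.intensity_bins + 1)
        base = enhanced_image(vol, seeds, params, intensity_edges=edges)
        shifted_vol = sc.CTVolume(vol.intensities + 37.0, vol.spacing)
        shifted = enhanced_image(shifted_vol, seeds, params, intensity_edges=edges + 37.0)
        np.testing.assert_allclose(base, shifted, atol=1e-10)

    def test_param_validation(self):
        with pytest.raises(ValueError):
            EnhancementParams(window=4)
        with pytest.raises(ValueError):
            EnhancementParams(sigma_floor=0.0)
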