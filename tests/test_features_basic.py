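"""Normalization, resampling, discretization, first-order and shape features."""

import numpy as np
import pytest

from conftest import make_mask, make_volume
from cribromics.features import (
    ExtractionSettings,
    approximate_bin_bounds,
    discretize_fixed_bin_width,
    extract_region_features,
    first_order_features,
    resample_image,
    shape_features,
    znormalize_image,
)
from cribromics.features.preprocessing import NormalizationError
from cribromics.features.shape import surface_area
from cribromics.grids import GridGeometry, RegionMask
from oracles import brute_first_order, brute_percentile


class TestZNormalize:
    def test_mean_zero_sd_scale(self, rng):
        img = make_volume(rng.normal(40, 7, size=(6, 6, 6)))
        out = znormalize_image(img, scale=100.0)
        assert out.data.mean() == pytest.approx(0.0, abs=1e-9)
        assert out.data.std() == pytest.approx(100.0, rel=1e-12)

    def test_already_standardized_image_is_scaled_only(self, rng):
        x = rng.normal(size=(5, 5, 5))
        x = (x - x.mean()) / x.std()
        out = znormalize_image(make_volume(x), scale=100.0)
        np.testing.assert_allclose(out.data, 100.0 * x, atol=1e-9)

    def test_flat_three_value_image_against_two_pass_oracle(self):
        x = np.array([1.0, 2.0, 3.0] * 9).reshape(3, 3, 3)
        out = znormalize_image(make_volume(x), scale=1.0)
        mean, sd = x.mean(), x.std()
        np.testing.assert_allclose(out.data, (x - mean) / sd, rtol=1e-12)

    def test_idempotent_at_scale_one(self, rng):
        img = make_volume(rng.normal(5, 2, size=(4, 4, 4)))
        once = znormalize_image(img, scale=1.0)
        twice = znormalize_image(once, scale=1.0)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-12)

    def test_constant_image_raises(self):
        with pytest.raises(NormalizationError):
            znormalize_image(make_volume(np.full((3, 3, 3), 7.0)))


class TestResampleImage:
    def test_native_spacing_preserves_values_at_centers(self, rng):
        img = make_volume(rng.normal(size=(6, 5, 4)))
        out = resample_image(img, (1.0, 1.0, 1.0))
        np.testing.assert_allclose(out.data, img.data, atol=1e-9)

    def test_linear_ramp_preserved_in_interior(self):
        # cubic B-spline reproduces a linear ramp; the mirror-boundary
        # prefilter kink decays geometrically (~0.27^d), so check deep interior
        ii = np.arange(40)[:, None, None]
        img = make_volume(np.broadcast_to(2.0 * ii + 1.0, (40, 8, 8)).copy())
        out = resample_image(img, (0.5, 1.0, 1.0))
        xs = 0.5 * np.arange(out.shape[0])
        interior = slice(24, -24)
        expect = 2.0 * xs[interior, None, None] + 1.0
        np.testing.assert_allclose(out.data[interior, 2:-2, 2:-2],
                                   np.broadcast_to(expect, out.data[interior, 2:-2, 2:-2].shape),
                                   rtol=1e-6)

    def test_binary_mask_stays_binary_under_nearest(self, rng):
        img = make_volume((rng.random((6, 6, 6)) < 0.5).astype(float))
        out = resample_image(img, (0.7, 0.7, 0.7), interpolator="nearest")
        assert set(np.unique(out.data)) <= {0.0, 1.0}

    def test_output_covers_original_extent(self):
        img = make_volume(np.ones((10, 10, 10)), spacing=(2.0, 2.0, 2.0))
        out = resample_image(img, (3.0, 3.0, 3.0))
        assert all(out.shape[ax] * 3.0 >= 20.0 for ax in range(3))


class TestDiscretize:
    def test_printed_range_to_bin_bounds(self):
        lo, hi = approximate_bin_bounds(6.81, 330.4, 3.0)
        assert round(lo, 2) == 2.27
        assert hi == pytest.approx(330.4 / 3.0)

    def test_enumerated_levels_width_three(self):
        d = discretize_fixed_bin_width(np.arange(7.0), 3.0)
        np.testing.assert_array_equal(d.gray_levels, [1, 1, 1, 2, 2, 2, 3])
        assert d.n_levels == 3

    def test_constant_region_single_level(self):
        d = discretize_fixed_bin_width(np.full(5, 42.0), 10.0)
        assert d.n_levels == 1 and set(d.gray_levels) == {1}

    def test_absolute_grid_anchoring(self):
        # bins anchored at multiples of the width, not at the region minimum
        d = discretize_fixed_bin_width(np.array([2.9, 3.1]), 3.0)
        np.testing.assert_array_equal(d.gray_levels, [1, 2])
        assert d.bin_interval(1) == (0.0, 3.0)

    def test_negative_values_supported(self):
        d = discretize_fixed_bin_width(np.array([-4.0, -1.0, 2.0]), 3.0)
        np.testing.assert_array_equal(d.gray_levels, [1, 2, 3])


class TestFirstOrder:
    def test_constant_region_degenerate_values(self):
        f = first_order_features(np.full(10, 3.5), bin_width=1.0)
        for k in ("Mean", "Median", "Minimum", "Maximum", "90Percentile"):
            assert f[k] == pytest.approx(3.5)
        assert f["Variance"] == 0.0 and f["Entropy"] == 0.0 and f["Uniformity"] == 1.0
        assert f["Skewness"] == 0.0 and f["Kurtosis"] == 0.0

    def test_ninetieth_percentile_matches_rank_interpolation_oracle(self, rng):
        for _ in range(10):
            x = rng.normal(size=rng.integers(5, 40))
            f = first_order_features(x, bin_width=0.5)
            assert f["90Percentile"] == pytest.approx(brute_percentile(x, 90), rel=1e-12)
            assert f["10Percentile"] == pytest.approx(brute_percentile(x, 10), rel=1e-12)

    def test_variance_identity_mean_of_squares(self, rng):
        x = rng.normal(3, 2, size=50)
        f = first_order_features(x, bin_width=1.0)
        assert f["Variance"] == pytest.approx((x ** 2).mean() - x.mean() ** 2, rel=1e-10)

    def test_all_statistics_match_brute_force_oracle(self, rng):
        x = rng.normal(10, 4, size=64)
        got = first_order_features(x, bin_width=2.0, voxel_volume_mm3=3.0)
        want = brute_first_order(x, 2.0)
        for k, v in want.items():
            assert got[k] == pytest.approx(v, rel=1e-9), k
        assert got["TotalEnergy"] == pytest.approx(3.0 * want["Energy"], rel=1e-12)

    def test_permutation_invariance(self, rng):
        x = rng.normal(size=30)
        a = first_order_features(x, 1.0)
        b = first_order_features(rng.permutation(x), 1.0)
        for k in a:  # equal up to float summation order
            assert a[k] == pytest.approx(b[k], rel=1e-12), k

    def test_percentile_monotone_under_new_maximum(self, rng):
        x = rng.normal(size=25)
        base = first_order_features(x, 1.0)["90Percentile"]
        grown = first_order_features(np.append(x, x.max() + 5.0), 1.0)["90Percentile"]
        assert grown >= base

    def test_single_voxel_rejected(self):
        with pytest.raises(ValueError):
            first_order_features(np.array([1.0]), 1.0)


class TestShape:
    def test_single_voxel_cube(self):
        vox = np.zeros((3, 3, 3), bool)
        vox[1, 1, 1] = True
        m = make_mask(vox, GridGeometry(spacing=(2.0, 2.0, 2.0)))
        assert m.volume_cc == pytest.approx(8.0 / 1000.0)
        assert surface_area(m, "voxel") == pytest.approx(6 * 4.0)

    def test_cuboid_face_count_surface_area(self):
        vox = np.zeros((7, 6, 5), bool)
        vox[1:6, 1:5, 1:4] = True  # 5 x 4 x 3 voxels, unit spacing
        m = make_mask(vox)
        f = shape_features(m, surface_method="voxel")
        assert f["VoxelVolume"] == pytest.approx(60.0)
        assert f["SurfaceArea"] == pytest.approx(2 * (20 + 15 + 12))  # 94

    def test_digitized_ball_sphericity_near_one(self):
        n, c, r = 27, 13, 10
        ii, jj, kk = np.mgrid[:n, :n, :n]
        ball = (ii - c) ** 2 + (jj - c) ** 2 + (kk - c) ** 2 <= r * r
        f = shape_features(make_mask(ball))
        assert f["Sphericity"] == pytest.approx(1.0, abs=0.05)

    def test_max_diameter_of_line_of_voxels(self):
        vox = np.zeros((10, 3, 3), bool)
        vox[1:9, 1, 1] = True
        f = shape_features(make_mask(vox, GridGeometry(spacing=(2.0, 1.0, 1.0))))
        assert f["Maximum3DDiameter"] == pytest.approx(14.0)  # 7 gaps * 2 mm

    def test_translation_invariance(self, rng):
        vox = np.zeros((12, 12, 8), bool)
        vox[2:6, 2:6, 1:4] = rng.random((4, 4, 3)) < 0.8
        a = shape_features(make_mask(vox))
        b = shape_features(make_mask(np.roll(vox, (4, 3, 2), axis=(0, 1, 2))))
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=1e-9), k

    def test_elongation_of_anisotropic_box(self):
        vox = np.zeros((22, 7, 4), bool)
        vox[1:21, 1:6, 1:3] = True
        f = shape_features(make_mask(vox))
        assert 0 < f["Elongation"] < 1
        assert f["MajorAxisLength"] > f["Maximum3DDiameter"] * 0.5


class TestExtraction:
    def test_feature_count_and_constant_adc_value(self, tiny_case):
        from cribromics.ivim import DwiStack, fit_segmented_ivim
        from cribromics.regions import filter_regions

        kept, _ = filter_regions(tiny_case.regions)
        adc = tiny_case.truth_adc.with_data(np.full(tiny_case.truth_adc.shape, 1.0e-3))
        fbv = tiny_case.truth_fbv
        feats = extract_region_features(tiny_case.t2w, adc, fbv, kept[0])
        assert len(feats) == 153
        # constant 1.00e-3 mm^2/s map reports 1.00 in 1e-3 units
        assert feats["adc_firstorder_90Percentile"] == pytest.approx(1.0)
        assert feats["adc_firstorder_Median"] == pytest.approx(1.0)

    def test_identical_voxel_multisets_identical_first_order(self, tiny_case):
        from cribromics.regions import filter_regions

        kept, _ = filter_regions(tiny_case.regions)
        reg = kept[0]
        feats1 = extract_region_features(tiny_case.t2w, tiny_case.truth_adc,
                                         tiny_case.truth_fbv, reg)
        feats2 = extract_region_features(tiny_case.t2w, tiny_case.truth_adc,
                                         tiny_case.truth_fbv, reg)
        assert feats1 == feats2  # bit-identical rerun

    def test_settings_validation(self):
        with pytest.raises(ValueError):
            ExtractionSettings(t2w_bin_width=0.0)


def test_expected_feature_names_match_extraction_output(tiny_case):
    from cribromics.features import expected_feature_names
    from cribromics.regions import filter_regions

    kept, _ = filter_regions(tiny_case.regions)
    feats = extract_region_features(tiny_case.t2w, tiny_case.truth_adc,
                                    tiny_case.truth_fbv, kept[0])
    assert list(feats) == expected_feature_names()
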