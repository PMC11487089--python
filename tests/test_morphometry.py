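"""Shape, intensity, density, and gradient quantification."""

import numpy as np
import pytest
from scipy import stats

from threemic import morphometry, synthgen
from threemic.core import GradientProfile, LabelMask, PointSet, SpheroidRecord
from threemic.errors import (
    CalibrationError,
    FitError,
    GeometryError,
    ObjectNotFoundError,
    SignalError,
    SpecError,
)
from threemic.synthgen import ShapeSpec


def rasterize_star(radius, amplitude, mode, phase, center, size, scale=1.0):
    """Independent rasterizer for r(θ) = R(1+A sin(kθ+φ)) at any placement."""
    rows, cols = np.mgrid[0:size, 0:size]
    dx, dy = cols - center[0], rows - center[1]
    rho = np.hypot(dx, dy)
    th = np.arctan2(dy, dx)
    inside = rho <= scale * radius * (1 + amplitude * np.sin(mode * th + phase))
    return LabelMask(inside.astype(np.int32))


class TestInvasivenessIndex:
    def test_disk_is_the_circular_minimum(self):
        mask = synthgen.make_spheroid_mask(ShapeSpec(radius_px=200, canvas_px=512))
        assert morphometry.invasiveness_index(mask) == pytest.approx(1.0, abs=0.02)

    def test_matches_analytic_polygon_oracle(self):
        n = 20000
        theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
        r = 150 * (1 + 0.3 * np.sin(8 * theta))
        x, y = r * np.cos(theta), r * np.sin(theta)
        perim = np.sum(np.hypot(np.diff(np.append(x, x[0])),
                                np.diff(np.append(y, y[0]))))
        area = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
        expected = perim / (2 * np.sqrt(np.pi * area))
        mask = rasterize_star(150, 0.3, 8, 0.0, (256, 256), 512)
        assert morphometry.invasiveness_index(mask) == pytest.approx(
            expected, rel=0.02)

    def test_invariant_to_placement_rotation_and_scale(self):
        base = rasterize_star(100, 0.3, 8, 0.0, (200, 200), 400)
        shifted = rasterize_star(100, 0.3, 8, 0.0, (150, 230), 400)
        rotated = rasterize_star(100, 0.3, 8, 1.1, (200, 200), 400)
        scaled = rasterize_star(100, 0.3, 8, 0.0, (200, 200), 400, scale=1.6)
        ref = morphometry.invasiveness_index(base)
        for variant in (shifted, rotated, scaled):
            assert morphometry.invasiveness_index(variant) == pytest.approx(
                ref, rel=0.02)

    def test_missing_or_tiny_labels_rejected(self):
        mask = LabelMask(np.zeros((32, 32), dtype=np.int32))
        with pytest.raises(ObjectNotFoundError):
            morphometry.invasiveness_index(mask, 1)
        mask.pixels[0, :10] = 1  # 10 px < minimum measurable object
        with pytest.raises(ObjectNotFoundError):
            morphometry.invasiveness_index(mask, 1)


def _record(num, den, mask=None):
    pixels = np.ones((20, 20), dtype=np.int32) if mask is None else mask
    return SpheroidRecord(LabelMask(pixels),
                          {"num": np.asarray(num, float),
                           "den": np.asarray(den, float)})


class TestFluorescenceRatio:
    def test_identical_channels_give_unity(self):
        img = np.random.default_rng(0).uniform(10, 20, (20, 20))
        assert morphometry.fluorescence_ratio(
            _record(img, img), "num", "den") == pytest.approx(1.0)

    def test_doubled_numerator_gives_two(self):
        img = np.full((20, 20), 7.0)
        assert morphometry.fluorescence_ratio(
            _record(2 * img, img), "num", "den") == pytest.approx(2.0)

    def test_background_median_is_subtracted(self):
        pixels = np.zeros((20, 20), dtype=np.int32)
        pixels[5:15, 5:15] = 1
        num = np.full((20, 20), 30.0)
        num[pixels == 1] = 130.0  # 100 above the 30 background
        den = np.full((20, 20), 30.0)
        den[pixels == 1] = 80.0   # 50 above background
        rec = SpheroidRecord(LabelMask(pixels), {"num": num, "den": den})
        assert morphometry.fluorescence_ratio(rec, "num", "den") == pytest.approx(2.0)

    def test_degenerate_denominator_rejected(self):
        with pytest.raises(SignalError):
            morphometry.fluorescence_ratio(
                _record(np.ones((20, 20)), np.zeros((20, 20))), "num", "den")

    def test_zero_cleaved_collagen_scores_zero(self):
        rec = SpheroidRecord(
            LabelMask(np.ones((10, 10), dtype=np.int32)),
            {"dq_collagen": np.zeros((10, 10)),
             "membrane": np.full((10, 10), 5.0)})
        assert morphometry.dq_collagen_score(rec) == pytest.approx(0.0)


def brute_force_delaunay(xy):
    """Empty-circumcircle oracle: every triangle whose circumcircle contains
    no other point, O(n^4)."""
    n = len(xy)
    tris = []
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                ax, ay = xy[i]; bx, by = xy[j]; cx, cy = xy[k]
                d = 2 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
                if abs(d) < 1e-12:
                    continue
                ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
                      + (cx**2 + cy**2) * (ay - by)) / d
                uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
                      + (cx**2 + cy**2) * (bx - ax)) / d
                r2 = (ax - ux) ** 2 + (ay - uy) ** 2
                empty = True
                for m in range(n):
                    if m in (i, j, k):
                        continue
                    if (xy[m, 0] - ux) ** 2 + (xy[m, 1] - uy) ** 2 < r2 - 1e-9:
                        empty = False
                        break
                if empty:
                    tris.append(tuple(sorted((i, j, k))))
    return set(tris)


class TestLocalDensity:
    def test_unit_square_corners(self):
        res = morphometry.local_density(
            PointSet([[0, 0], [1, 0], [0, 1], [1, 1]]))
        assert len(res.densities) == 2
        assert np.allclose(sorted(res.densities), [2.0, 2.0])

    def test_matches_brute_force_empty_circumcircle_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            xy = rng.uniform(0, 10, (12, 2))
            res = morphometry.local_density(PointSet(xy))
            got = {tuple(sorted(t)) for t in res.triangles}
            assert got == brute_force_delaunay(xy)

    def test_triangle_areas_tile_the_convex_hull(self):
        from scipy.spatial import ConvexHull

        xy = np.random.default_rng(3).uniform(0, 50, (40, 2))
        res = morphometry.local_density(PointSet(xy))
        assert res.areas.sum() == pytest.approx(ConvexHull(xy).volume)

    def test_density_scales_as_inverse_square_of_coordinates(self):
        xy = np.random.default_rng(4).uniform(0, 10, (20, 2))
        a = morphometry.local_density(PointSet(xy))
        b = morphometry.local_density(PointSet(3.0 * xy))
        assert b.mean_density == pytest.approx(a.mean_density / 9.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(GeometryError):
            morphometry.local_density(PointSet([[0, 0], [1, 1]]))
        with pytest.raises(GeometryError):
            morphometry.local_density(
                PointSet([[0, 0], [1, 1], [2, 2], [3, 3]]))


class TestDensityTimecourse:
    def test_static_points_give_constant_series(self):
        pts = synthgen.make_nuclei_points(25, (40, 40), dispersion=2.0, seed=1)
        series = morphometry.density_timecourse([pts] * 4)
        assert np.allclose(series.value, series.value[0])

    def test_radial_expansion_decays_as_scale_squared(self):
        pts = synthgen.make_nuclei_points(30, (40, 40), dispersion=3.0, seed=2)
        frames = [PointSet(pts.xy * 1.1**t) for t in range(5)]
        series = morphometry.density_timecourse(frames)
        expected = series.value[0] * 1.1 ** (-2 * np.arange(5))
        assert np.allclose(series.value, expected, rtol=1e-9)

    def test_dispersing_vs_static_contrast(self):
        pts = synthgen.make_nuclei_points(30, (40, 40), dispersion=3.0, seed=2)
        disp = morphometry.density_timecourse(
            [PointSet(pts.xy * 1.1**t) for t in range(5)])
        static = morphometry.density_timecourse([pts] * 5)
        assert np.all(np.diff(disp.value) < 0)
        assert np.allclose(np.diff(static.value), 0)


class TestPhCalibration:
    def test_anchors_round_trip_exactly(self):
        curve = morphometry.calibrate_ph([0.7, 1.0, 1.5, 2.0],
                                         [8.0, 7.4, 6.9, 6.4])
        vals, clamped = curve(np.array([0.7, 1.5]))
        assert np.allclose(vals, [8.0, 6.9])
        assert not clamped.any()

    def test_linear_map_interpolates_linearly(self):
        curve = morphometry.calibrate_ph([1.0, 2.0, 3.0], [7.0, 6.0, 5.0])
        vals, _ = curve(np.array([1.5, 2.25]))
        assert np.allclose(vals, [6.5, 5.75], atol=1e-9)

    def test_out_of_range_queries_clamped_and_flagged(self):
        curve = morphometry.calibrate_ph([1.0, 2.0, 3.0], [7.0, 6.0, 5.0])
        vals, clamped = curve(np.array([0.5, 3.5]))
        assert np.allclose(vals, [7.0, 5.0])
        assert clamped.all()

    def test_non_monotone_anchors_rejected(self):
        with pytest.raises(CalibrationError):
            morphometry.calibrate_ph([1.0, 2.0, 1.5], [7, 6, 5])
        with pytest.raises(CalibrationError):
            morphometry.calibrate_ph([1.0, 2.0], [7, 6])


class TestPhProfile:
    curve = morphometry.calibrate_ph([0.7, 0.9, 1.2, 1.6, 2.0],
                                     [8.0, 7.6, 7.2, 6.8, 6.4])

    def test_flat_image_gives_flat_profile(self):
        prof = GradientProfile([0.0, 10.0], [1.2, 1.2])
        img = synthgen.make_gradient_image(10.0, prof, noise_sd=0.0)
        est = morphometry.estimate_ph_profile(img, self.curve)
        assert np.allclose(est.value, 7.2, atol=1e-6)

    def test_decreasing_ph_recovered_within_noise(self):
        d = np.linspace(0, 10, 21)
        ph_true = 7.4 - 0.06 * d
        ratio = np.interp(ph_true, [6.4, 6.8, 7.2, 7.6, 8.0],
                          [2.0, 1.6, 1.2, 0.9, 0.7])
        img = synthgen.make_gradient_image(
            10.0, GradientProfile(d, ratio), noise_sd=1.0, seed=5)
        est = morphometry.estimate_ph_profile(img, self.curve)
        expected = np.interp(est.distance_mm, d, ph_true)
        assert np.allclose(est.value, expected, atol=0.05)

    def test_consumer_vs_no_consumer_contrast(self):
        d = np.linspace(0, 10, 21)
        flat = synthgen.make_gradient_image(
            10.0, GradientProfile(d, np.full_like(d, 0.9)), seed=1)
        falling = synthgen.make_gradient_image(
            10.0, GradientProfile(d, 0.9 + 0.1 * d), seed=1)
        est_flat = morphometry.estimate_ph_profile(flat, self.curve)
        est_fall = morphometry.estimate_ph_profile(falling, self.curve)
        fit_flat = morphometry.gradient_fit(est_flat.distance_mm, est_flat.value)
        fit_fall = morphometry.gradient_fit(est_fall.distance_mm, est_fall.value)
        assert abs(fit_flat.slope) < 0.005
        assert fit_fall.slope < -0.03

    def test_missing_channel_rejected(self):
        prof = GradientProfile([0.0, 10.0], [1.2, 1.2])
        img = synthgen.make_gradient_image(10.0, prof,
                                           channel_names=("a", "b"))
        with pytest.raises(SignalError):
            morphometry.estimate_ph_profile(img, self.curve)


class TestDegradationScore:
    def test_identical_images_score_zero(self):
        img = np.full((30, 30), 10.0)
        mask = np.ones((30, 30), bool)
        assert morphometry.degradation_score(img, img, mask) == 0.0

    def test_recovers_constructed_dark_fraction(self):
        rng = np.random.default_rng(0)
        ref = rng.uniform(50, 60, (50, 50))
        sample = ref.copy()
        mask = np.ones_like(ref, bool)
        dark = rng.random(ref.shape) < 0.3
        sample[dark] = 0.0
        score = morphometry.degradation_score(sample, ref, mask)
        assert score == pytest.approx(dark.mean(), abs=0.01)

    def test_empty_mask_rejected(self):
        img = np.ones((5, 5))
        with pytest.raises(SpecError):
            morphometry.degradation_score(img, img, np.zeros((5, 5), bool))


class TestDrugConcentration:
    def test_source_bin_returns_c0(self):
        prof = synthgen.make_decay_profile(150.0, 5.0, 10.0)
        conc = morphometry.estimate_drug_concentration(prof, 150.0)
        assert conc.value[0] == pytest.approx(150.0)

    def test_thirty_percent_intensity_at_150_gives_45(self):
        prof = GradientProfile([0.0, 5.0, 10.0], [200.0, 100.0, 60.0])
        conc = morphometry.estimate_drug_concentration(prof, 150.0)
        assert conc.value[-1] == pytest.approx(45.0)

    def test_equals_scaled_normalized_profile_pointwise(self):
        prof = synthgen.make_decay_profile(80.0, 3.0, 12.0)
        conc = morphometry.estimate_drug_concentration(prof, 120.0)
        assert np.allclose(conc.value, 120.0 * prof.value / prof.value[0])

    def test_linear_in_c0_and_intensity_scale_invariant(self):
        prof = synthgen.make_decay_profile(10.0, 4.0, 12.0)
        scaled = GradientProfile(prof.distance_mm, 7.3 * prof.value)
        a = morphometry.estimate_drug_concentration(prof, 100.0)
        b = morphometry.estimate_drug_concentration(prof, 200.0)
        c = morphometry.estimate_drug_concentration(scaled, 100.0)
        assert np.allclose(2 * a.value, b.value)
        assert np.allclose(a.value, c.value)

    def test_noisy_profile_is_monotonized_and_flagged(self):
        prof = GradientProfile([0, 1, 2, 3], [100.0, 80.0, 85.0, 60.0])
        conc = morphometry.estimate_drug_concentration(prof, 100.0)
        assert conc.flags["monotonized"]
        assert np.all(np.diff(conc.value) <= 1e-9)

    def test_zero_source_intensity_rejected(self):
        prof = GradientProfile([0, 1], [0.0, 0.0])
        with pytest.raises(SignalError):
            morphometry.estimate_drug_concentration(prof, 100.0)


class TestGradientFit:
    def test_exact_line_recovered(self):
        x = np.arange(10, dtype=float)
        fit = morphometry.gradient_fit(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r == pytest.approx(1.0)

    def test_permutation_null_centers_r_at_zero(self):
        rng = np.random.default_rng(1)
        x = np.arange(30, dtype=float)
        y = 0.5 * x + rng.normal(0, 1, 30)
        rs = [morphometry.gradient_fit(x, rng.permutation(y)).r
              for _ in range(200)]
        assert abs(np.mean(rs)) < 3 / np.sqrt(30 * 200)

    def test_noisy_slope_within_2se_and_se_matches_closed_form(self):
        rng = np.random.default_rng(7)
        x = np.linspace(0, 10, 50)
        sd = 1.5
        y = 0.5 * x + rng.normal(0, sd, 50)
        fit = morphometry.gradient_fit(x, y)
        assert abs(fit.slope - 0.5) < 2 * fit.slope_se
        resid = y - (fit.intercept + fit.slope * x)
        s2 = np.sum(resid**2) / (len(x) - 2)
        se_closed = np.sqrt(s2 / np.sum((x - x.mean()) ** 2))
        assert fit.slope_se == pytest.approx(se_closed, rel=1e-9)

    def test_two_group_t_test_and_three_group_anova(self):
        rng = np.random.default_rng(2)
        x = np.tile(np.arange(10.0), 3)
        y = np.concatenate([rng.normal(0, 1, 10), rng.normal(0, 1, 10),
                            rng.normal(3, 1, 10)])
        g2 = np.repeat(["a", "b"], 15)
        fit2 = morphometry.gradient_fit(x, y, groups=g2)
        assert fit2.group_test["test"] == "t"
        t_ref, p_ref = stats.ttest_ind(y[:15], y[15:])
        assert fit2.group_test["p_value"] == pytest.approx(p_ref)
        g3 = np.repeat(["a", "b", "c"], 10)
        fit3 = morphometry.gradient_fit(x, y, groups=g3)
        assert fit3.group_test["test"] == "anova+tukey"
        assert fit3.group_test["p_value"] < 0.001
        assert fit3.group_test["tukey_p"]["a|b"] > 0.05
        assert fit3.group_test["tukey_p"]["a|c"] < 0.01

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(FitError):
            morphometry.gradient_fit([1, 2], [1, 2])
        with pytest.raises(FitError):
            morphometry.gradient_fit([3, 3, 3], [1, 2, 3])


class TestClassifyRegion:
    @pytest.mark.parametrize("d,expected", [
        (0.0, "proximal"),
        (2.0, "proximal"),      # boundary is inclusive: "2 mm or closer"
        (2.001, "intermediate"),
        (8.0, "intermediate"),  # distal starts strictly beyond 8 mm
        (9.5, "distal"),
    ])
    def test_region_boundaries(self, d, expected):
        assert morphometry.classify_region(d) == expected

    def test_negative_distance_rejected(self):
        with pytest.raises(SpecError):
            morphometry.classify_region(-0.1)
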