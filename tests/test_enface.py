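import numpy as np
import pytest

from golgimap import enface, image_core
from golgimap.enface import (
    AnalysisError,
    CANVAS_CENTER,
    CANVAS_SIZE,
    EnFaceAverage,
    MiniStack,
    NormalizedMiniStack,
    RadialProfile,
    align_ministack,
    average_ministacks,
    extract_all_radii,
    extract_marker_radius,
    gyradius,
    measure_ring_diameter,
    normalize_ministack,
    radial_mean_profile,
    summarize_radii,
)
from golgimap.image_core import MultiChannelImage, Point, center_of_mass
from golgimap.synthetic import SceneSpec, StructureSpec, render_scene

from conftest import brute_annular_means, brute_gyradius


def make_ring(center=(63.5, 63.5), radius=40.0, width=2.0, size=128, channel="giantin",
              extra=(), psf=0.0, seed=0, poisson=False):
    structures = [
        StructureSpec(channel, "ring", center, 1e4, radius_px=radius, ring_width_px=width)
    ] + list(extra)
    spec = SceneSpec(size, 50.0, structures, psf_sigma_nm=psf, seed=seed,
                     poisson_noise=poisson)
    img, truth = render_scene(spec)
    return img, truth


class TestGyradius:
    def test_thin_ring_equals_radius(self):
        img, _ = make_ring(radius=50.0, width=1.0)
        arr = img.channel("giantin")
        c = center_of_mass(arr)
        assert gyradius(arr, c) == pytest.approx(50.0, abs=0.2)

    def test_uniform_disk_r_over_sqrt2(self):
        spec = SceneSpec(256, 50.0,
                         [StructureSpec("g", "disk", (127.5, 127.5), 1e4, radius_px=100)],
                         psf_sigma_nm=0.0)
        img, _ = render_scene(spec)
        arr = img.channel("g")
        c = center_of_mass(arr)
        assert gyradius(arr, c) == pytest.approx(100 / np.sqrt(2), abs=0.3)

    def test_single_pixel_at_center_is_zero(self):
        arr = np.zeros((20, 20))
        arr[10, 10] = 5.0
        assert gyradius(arr, Point(10, 10)) == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        arr = rng.uniform(0, 2, size=(25, 25))
        c = Point(12.3, 11.1)
        assert gyradius(arr, c) == pytest.approx(brute_gyradius(arr, 12.3, 11.1), abs=1e-9)

    def test_zero_intensity_errors(self):
        with pytest.raises(AnalysisError, match="zero"):
            gyradius(np.zeros((10, 10)), Point(5, 5))

    def test_scale_equivariance(self):
        # scaling the geometry by k scales the gyradius by k
        img1, _ = make_ring(radius=25.0, width=2.0)
        img2, _ = make_ring(radius=50.0, width=4.0)
        g1 = gyradius(img1.channel("giantin"), center_of_mass(img1.channel("giantin")))
        g2 = gyradius(img2.channel("giantin"), center_of_mass(img2.channel("giantin")))
        assert g2 / g1 == pytest.approx(2.0, rel=0.01)


class TestNormalize:
    def test_gyradius_50_scales_to_100(self):
        img, _ = make_ring(radius=50.0, width=1.0)
        nms = normalize_ministack(MiniStack(img, "giantin"))
        assert nms.reference_gyradius_px == pytest.approx(100.0, abs=0.5)
        assert nms.scale_factor == pytest.approx(2.0, rel=0.01)

    def test_canvas_is_701(self):
        img, _ = make_ring(radius=30.0)
        nms = normalize_ministack(MiniStack(img, "giantin"))
        assert nms.image.shape == (CANVAS_SIZE, CANVAS_SIZE)

    def test_identity_when_already_100(self):
        img, _ = make_ring(radius=100.0, width=1.0, size=256, center=(127.5, 127.5))
        nms = normalize_ministack(MiniStack(img, "giantin"), normalize_intensity=False)
        assert nms.scale_factor == pytest.approx(1.0, rel=0.01)

    def test_intensity_normalization_sums_to_one(self):
        img, _ = make_ring(radius=40.0)
        nms = normalize_ministack(MiniStack(img, "giantin"))
        assert nms.image.channel("giantin").sum() == pytest.approx(1.0, rel=1e-6)

    def test_all_channels_share_the_scale(self):
        inner = StructureSpec("marker", "disk", (63.5, 63.5), 1e4, radius_px=20)
        img, _ = make_ring(radius=40.0, extra=[inner])
        nms = normalize_ministack(MiniStack(img, "giantin"))
        m = nms.image.channel("marker")
        g_m = gyradius(m, center_of_mass(m))
        # disk gyradius R/sqrt2 scaled by the reference's factor
        assert g_m == pytest.approx(20 / np.sqrt(2) * nms.scale_factor, rel=0.02)

    def test_oversized_structure_errors(self):
        # gyradius ~15 -> scale ~6.7: a 256-px image would overflow the canvas
        img, _ = make_ring(radius=15.0, width=1.0, size=256, center=(127.5, 127.5),
                           extra=[StructureSpec("marker", "ring", (127.5, 127.5), 1e4,
                                                radius_px=110, ring_width_px=2)])
        with pytest.raises(AnalysisError, match="outside"):
            normalize_ministack(MiniStack(img, "giantin"))

    def test_idempotent_within_half_pixel(self):
        img, _ = make_ring(radius=37.0)
        nms = normalize_ministack(MiniStack(img, "giantin"))
        again = normalize_ministack(
            MiniStack(nms.image, "giantin"), normalize_intensity=False
        )
        assert abs(again.reference_gyradius_px - nms.reference_gyradius_px) < 0.5


class TestAlign:
    def _off_center_canvas_ring(self, cx=340.0, cy=355.0):
        spec = SceneSpec(
            CANVAS_SIZE, 50.0,
            [StructureSpec("giantin", "ring", (cx, cy), 1e4, radius_px=100,
                           ring_width_px=2)],
            psf_sigma_nm=0.0,
        )
        img, _ = render_scene(spec)
        return NormalizedMiniStack(img, "giantin", 1.0, 100.0)

    def test_centroid_moved_to_350(self):
        nms = self._off_center_canvas_ring()
        out = align_ministack(nms)
        c = center_of_mass(out.image.channel("giantin"))
        assert c.x == pytest.approx(CANVAS_CENTER, abs=0.25)
        assert c.y == pytest.approx(CANVAS_CENTER, abs=0.25)
        assert out.shift_px[0] == pytest.approx(10.0, abs=0.25)
        assert out.shift_px[1] == pytest.approx(-5.0, abs=0.25)

    def test_already_centered_zero_shift(self):
        nms = self._off_center_canvas_ring(350.0, 350.0)
        out = align_ministack(nms)
        assert np.hypot(*out.shift_px) < 0.25
        np.testing.assert_allclose(
            out.image.channel("giantin"), nms.image.channel("giantin"), atol=1e-9
        )

    def test_rigid_common_shift_preserves_channel_offset(self):
        spec = SceneSpec(
            CANVAS_SIZE, 50.0,
            [
                StructureSpec("giantin", "ring", (340.0, 350.0), 1e4, radius_px=100,
                              ring_width_px=2),
                StructureSpec("marker", "disk", (360.0, 350.0), 1e4, radius_px=30),
            ],
            psf_sigma_nm=0.0,
        )
        img, _ = render_scene(spec)
        nms = NormalizedMiniStack(img, "giantin", 1.0, 100.0)
        out = align_ministack(nms)
        cg = center_of_mass(out.image.channel("giantin"))
        cm = center_of_mass(out.image.channel("marker"))
        assert cm.x - cg.x == pytest.approx(20.0, abs=0.1)

    def test_realign_idempotent(self):
        out = align_ministack(self._off_center_canvas_ring())
        out2 = align_ministack(out)
        assert np.hypot(*out2.shift_px) < 0.25


class TestAverage:
    def test_copies_average_to_themselves(self):
        nms = TestAlign()._off_center_canvas_ring()
        avg = average_ministacks([nms, nms, nms])
        np.testing.assert_allclose(
            avg.image.channel("giantin"), nms.image.channel("giantin"), rtol=1e-12
        )
        assert avg.n == 3

    def test_channel_mismatch_errors(self):
        a = TestAlign()._off_center_canvas_ring()
        other = MultiChannelImage({"different": a.image.channel("giantin")}, 50.0)
        b = NormalizedMiniStack(other, "different", 1.0, 100.0)
        with pytest.raises(AnalysisError, match="channel sets differ"):
            average_ministacks([a, b])

    def test_empty_errors(self):
        with pytest.raises(AnalysisError, match="no aligned"):
            average_ministacks([])


class TestRadialProfile:
    def test_thin_ring_peak_at_radius(self):
        img, _ = make_ring(center=(63.5, 63.5), radius=40.0, width=1.0)
        c = center_of_mass(img.channel("giantin"))
        prof = radial_mean_profile(img, c, max_radius=60)
        peak_r = prof.radii_px[np.argmax(prof.values["giantin"])]
        assert abs(peak_r - 40) <= 1

    def test_matches_brute_force_annuli(self):
        rng = np.random.default_rng(8)
        arr = rng.uniform(0, 3, size=(41, 41))
        img = MultiChannelImage({"a": arr}, 50.0)
        prof = radial_mean_profile(img, Point(20.2, 19.7), max_radius=15)
        oracle = brute_annular_means(arr, 20.2, 19.7, 15)
        np.testing.assert_allclose(prof.values["a"], oracle, atol=1e-9)

    def test_uniform_disk_flat_then_zero(self):
        spec = SceneSpec(256, 50.0,
                         [StructureSpec("g", "disk", (127.5, 127.5), 1e6, radius_px=100)],
                         psf_sigma_nm=0.0)
        img, _ = render_scene(spec)
        prof = radial_mean_profile(img, Point(127.5, 127.5), max_radius=120)
        v = prof.values["g"]
        inner = v[:94]  # r = 1..94
        assert inner.std() / inner.mean() < 0.01
        assert np.all(v[105:] == 0)

    def test_normalized_max_is_one(self):
        img, _ = make_ring()
        prof = radial_mean_profile(img, center_of_mass(img.channel("giantin")),
                                   max_radius=60).normalize()
        assert prof.values["giantin"].max() == pytest.approx(1.0)

    def test_center_outside_errors(self):
        img, _ = make_ring()
        with pytest.raises(AnalysisError, match="outside"):
            radial_mean_profile(img, Point(1000, 1000))

    def test_full_default_range_is_350(self):
        spec = SceneSpec(CANVAS_SIZE, 50.0,
                         [StructureSpec("g", "ring", (350.0, 350.0), 1e4,
                                        radius_px=100, ring_width_px=2)],
                         psf_sigma_nm=0.0)
        img, _ = render_scene(spec)
        prof = radial_mean_profile(img, Point(350, 350))
        assert len(prof.radii_px) == 350
        assert prof.radii_px[0] == 1 and prof.radii_px[-1] == 350


class TestExtractMarkerRadius:
    def _profile(self, values, channel="g"):
        radii = np.arange(1, len(values) + 1)
        return RadialProfile(radii, {channel: np.asarray(values, float)},
                             Point(0, 0), 50.0)

    def test_triangular_profile_hand_computed(self):
        # p(r) = max(0, 10 - |r - 100|): peak 10 at r=100, half-max 5 at r=105
        r = np.arange(1, 201)
        p = np.maximum(0.0, 10.0 - np.abs(r - 100))
        mr = extract_marker_radius(self._profile(p), "g")
        assert mr.peak_radius_px == 100
        assert mr.radius_px == pytest.approx(105.0, abs=1e-9)
        assert mr.half_max_value == pytest.approx(5.0)

    def test_gaussian_profile_closed_form(self):
        # half-max of a Gaussian bump sits at r0 + sigma*sqrt(2 ln 2)
        r0, sigma = 80.0, 12.0
        r = np.arange(1, 301, dtype=float)
        p = np.exp(-((r - r0) ** 2) / (2 * sigma**2))
        mr = extract_marker_radius(self._profile(p), "g")
        assert mr.radius_px == pytest.approx(r0 + sigma * np.sqrt(2 * np.log(2)),
                                             abs=0.05)

    def test_reference_channel_normalized_to_one(self):
        r = np.arange(1, 201)
        p = np.maximum(0.0, 10.0 - np.abs(r - 100.0))
        prof = RadialProfile(r, {"giantin": p, "m": np.maximum(0.0, 6.0 - np.abs(r - 50.0))},
                             Point(0, 0), 50.0)
        records = extract_all_radii(prof, "giantin")
        by = {rec.channel_name: rec for rec in records}
        assert by["giantin"].radius_normalized == 1.0
        assert by["m"].radius_normalized == pytest.approx(53.0 / 105.0, abs=1e-9)

    def test_unresolved_outer_slope_errors(self):
        p = np.linspace(1, 10, 50)  # monotone rising, never falls below half
        with pytest.raises(AnalysisError, match="outer slope"):
            extract_marker_radius(self._profile(p), "g")

    def test_half_max_plateau_outermost_sample(self):
        # exact half-max plateau at r=5..7 resolves to the outermost sample r=7
        p = np.array([0, 0, 10, 10, 5, 5, 5, 0, 0], dtype=float)
        mr = extract_marker_radius(self._profile(p), "g")
        assert mr.radius_px == pytest.approx(7.0)  # last plateau sample before drop


class TestRingDiameter:
    def test_hand_computed_profile(self):
        # sparse double peak: half-max crossings at positions 4 and 16 -> 12 px
        arr = np.zeros((21, 21))
        row = 10
        arr[row, 4] = 5.0
        arr[row, 5] = 10.0
        arr[row, 6] = 5.0
        arr[row, 14] = 5.0
        arr[row, 15] = 10.0
        arr[row, 16] = 5.0
        img = MultiChannelImage({"g": arr}, 50.0)
        d_px, d_nm = measure_ring_diameter(img, "g", Point(10, 10), angle_deg=0.0)
        assert d_px == pytest.approx(12.0, abs=1e-6)
        assert d_nm == pytest.approx(12.0 * 50.0)

    def test_planted_annulus_any_angle(self):
        img, truth = make_ring(center=(63.5, 63.5), radius=40.0, width=3.0)
        outer_d = truth.records[0]["outer_diameter_px"]
        for angle in (0.0, 30.0, 45.0, 77.0, 90.0):
            d_px, _ = measure_ring_diameter(img, "giantin", Point(63.5, 63.5),
                                            angle_deg=angle)
            assert d_px == pytest.approx(outer_d, abs=1.0)

    def test_multi_angle_mean(self):
        img, truth = make_ring(center=(63.5, 63.5), radius=40.0, width=3.0)
        outer_d = truth.records[0]["outer_diameter_px"]
        d_px, d_nm = measure_ring_diameter(img, "giantin", Point(63.5, 63.5))
        assert d_px == pytest.approx(outer_d, abs=1.0)
        assert d_nm == pytest.approx(d_px * 50.0)

    def test_no_flanking_peaks_errors(self):
        arr = np.zeros((31, 31))
        arr[15, 15] = 10.0  # single central blob, no ring
        img = MultiChannelImage({"g": arr}, 50.0)
        with pytest.raises(AnalysisError):
            measure_ring_diameter(img, "g", Point(15, 15), angle_deg=0.0)


class TestSummarizeRadii:
    def _rec(self, channel, value):
        from golgimap.enface import MarkerRadius

        return MarkerRadius(channel, value * 100, value, 100.0, 5.0)

    def test_single_record_sem_empty(self):
        out = summarize_radii([self._rec("m", 0.5)])
        assert out.loc[0, "normalized_radius_mean"] == 0.5
        assert np.isnan(out.loc[0, "normalized_radius_sem"])
        assert out.loc[0, "n"] == 1

    def test_two_records_hand_computed(self):
        out = summarize_radii([self._rec("m", 0.4), self._rec("m", 0.6)])
        assert out.loc[0, "normalized_radius_mean"] == pytest.approx(0.5)
        assert out.loc[0, "normalized_radius_sem"] == pytest.approx(0.1, abs=1e-9)
        assert out.loc[0, "n"] == 2

    def test_lq_join_and_missing_flag(self):
        out = summarize_radii(
            [self._rec("m", 0.5), self._rec("q", 0.7)], lq_table={"m": 0.53}
        )
        by = out.set_index("channel")
        assert by.loc["m", "lq"] == 0.53 and not by.loc["m", "lq_missing"]
        assert np.isnan(by.loc["q", "lq"]) and by.loc["q", "lq_missing"]
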