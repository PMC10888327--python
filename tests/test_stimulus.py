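"""Plate geometry and rendering: unit conversions, packing, arrow
placement, luminance masking and the hit test."""

import math

import numpy as np
import pytest
from scipy import stats

from chromathresh.colorimetry import confusion_pair, rgb_to_lab, delta_e
from chromathresh.stimulus import (
    ARROW_LENGTH_DEG,
    ARROW_CENTER_MAX_DEG,
    CIRCLE_DIAMETER_RANGE_DEG,
    PlateStimulus,
    ViewingGeometry,
    deg_to_px,
    is_hit,
    make_catch_plate,
    make_plate,
    pack_circles,
    packing_coverage,
    place_arrow,
    render_plate,
)
from chromathresh.stimulus import _point_segment_distance


class TestDegToPx:
    def test_zero_angle(self, geom):
        assert deg_to_px(0.0, geom) == 0.0

    def test_pixel_pitch_closed_form(self, geom):
        # diagonal px = sqrt(2736^2 + 1824^2); pitch = 12.3 in / that
        diag_px = math.hypot(2736, 1824)
        expected = 12.3 * 25.4 / diag_px
        assert geom.pixel_pitch_mm == pytest.approx(expected, rel=1e-12)
        assert geom.pixel_pitch_mm == pytest.approx(0.0950, abs=5e-4)

    def test_arrow_extent_closed_form(self, geom):
        # 4.26 deg at 50 cm: 2 * 500 mm * tan(2.13 deg)
        expected_mm = 2 * 500 * math.tan(math.radians(2.13))
        assert geom.deg_to_cm(4.26) * 10 == pytest.approx(expected_mm, rel=1e-12)
        assert expected_mm == pytest.approx(37.2, abs=0.05)

    def test_round_trip(self, geom):
        assert geom.px_to_deg(geom.deg_to_px(3.21)) == pytest.approx(3.21, rel=1e-12)

    def test_rejects_wide_angles(self, geom):
        with pytest.raises(ValueError):
            deg_to_px(95.0, geom)


REGION = (0.0, 0.0, 420.0, 420.0)


class TestPackCircles:
    def test_deterministic_given_seed(self, geom):
        a = pack_circles(REGION, rng_seed=7, geom=geom)
        b = pack_circles(REGION, rng_seed=7, geom=geom)
        assert a == b
        c = pack_circles(REGION, rng_seed=8, geom=geom)
        assert a != c

    def test_no_overlaps_brute_force(self, geom):
        circles = pack_circles(REGION, rng_seed=3, geom=geom)
        pts = np.array([geom.deg_to_px(c.center[0]) for c in circles])
        pys = np.array([geom.deg_to_px(c.center[1]) for c in circles])
        rs = np.array([geom.deg_to_px(c.radius_deg) for c in circles])
        dx = pts[:, None] - pts[None, :]
        dy = pys[:, None] - pys[None, :]
        dist = np.sqrt(dx**2 + dy**2)
        lim = rs[:, None] + rs[None, :]
        np.fill_diagonal(dist, np.inf)
        assert np.all(dist >= lim - 1e-9)

    def test_radii_within_bounds_and_jitter_range(self, geom):
        circles = pack_circles(REGION, rng_seed=3, geom=geom)
        lo, hi = CIRCLE_DIAMETER_RANGE_DEG
        for c in circles:
            assert lo / 2 - 1e-9 <= c.radius_deg <= hi / 2 + 1e-9
            assert 0.4 <= c.luminance_factor <= 1.6

    def test_coverage_reaches_target_full_screen(self, geom):
        d = geom.display
        region = (0.0, 0.0, float(d.width_px), float(d.height_px))
        circles = pack_circles(region, rng_seed=1, geom=geom)
        assert packing_coverage(circles, region, geom) >= 0.55 - 1e-6


class TestPlaceArrow:
    def test_deterministic(self, geom):
        assert place_arrow(11, geom) == place_arrow(11, geom)

    def test_direction_presets_and_centrality(self, geom):
        rng = np.random.default_rng(0)
        directions = []
        for _ in range(2000):
            p = place_arrow(rng, geom)
            directions.append(p.direction_deg)
            assert p.direction_deg in {45.0 * k for k in range(8)}
            th = math.radians(p.direction_deg)
            u = np.array([math.cos(th), math.sin(th)])
            c = np.array(p.center_deg)
            d = _point_segment_distance(
                np.zeros(2), c - ARROW_LENGTH_DEG / 2 * u, c + ARROW_LENGTH_DEG / 2 * u
            )
            assert d < ARROW_CENTER_MAX_DEG
            half_w, half_h = geom.screen_half_extent_deg
            poly = np.array(p.polygon_deg)
            assert np.all(np.abs(poly[:, 0]) <= half_w)
            assert np.all(np.abs(poly[:, 1]) <= half_h)

    def test_direction_uniformity_chi2(self, geom):
        rng = np.random.default_rng(42)
        dirs = [place_arrow(rng, geom).direction_deg for _ in range(10_000)]
        counts = np.bincount((np.array(dirs) / 45).astype(int), minlength=8)
        _, p = stats.chisquare(counts)
        assert p > 0.001

    def test_head_center_is_tip(self, geom):
        p = place_arrow(5, geom)
        assert p.head_center_deg == p.polygon_deg[3]


@pytest.fixture(scope="module")
def central_circles(geom):
    d = geom.display
    cx, cy = d.width_px / 2, d.height_px / 2
    return pack_circles((cx - 300, cy - 300, cx + 300, cy + 300), rng_seed=5, geom=geom)


class TestRenderPlate:
    def test_zero_de_arrow_invisible(self, geom, central_circles):
        pair = confusion_pair("deutan", 0.0, display=geom.display)
        plate, img = render_plate(pair, circles=central_circles, rng_seed=2, geom=geom)
        arrow = [c for c in plate.circles if c.role == "arrow"]
        bg = [c for c in plate.circles if c.role == "background"]
        assert arrow and bg
        assert pair.arrow_xy == pytest.approx(pair.background_xy, abs=1e-12)

    def test_rendered_chromaticity_matches_role(self, geom, central_circles):
        pair = confusion_pair("tritan", 30.0, display=geom.display)
        plate, img = render_plate(pair, circles=central_circles, rng_seed=2, geom=geom)
        d = geom.display
        checked = 0
        for c in plate.circles[::25]:
            px, py = geom.deg_xy_to_px(c.center)
            rgb = img[int(round(py)), int(round(px))] / 255.0
            lab = rgb_to_lab(rgb, d)
            xyz = d.rgb_to_xyz_matrix @ d.eotf(rgb)
            s = xyz.sum()
            if s <= 0:
                continue
            xy = (xyz[0] / s, xyz[1] / s)
            target = pair.arrow_xy if c.role == "arrow" else pair.background_xy
            # 8-bit quantization limits chromaticity fidelity
            assert xy == pytest.approx(target, abs=0.01)
            checked += 1
        assert checked > 20

    def test_luminance_jitter_masks_roles(self, geom, central_circles):
        pair = confusion_pair("deutan", 40.0, display=geom.display)
        plate, _ = render_plate(pair, circles=central_circles, rng_seed=2, geom=geom)
        fa = [c.luminance_factor for c in plate.circles if c.role == "arrow"]
        fb = [c.luminance_factor for c in plate.circles if c.role == "background"]
        ks, _ = stats.ks_2samp(fa, fb)
        assert ks < 0.25  # same Uniform(0.4, 1.6) by construction

    def test_determinism_bit_identical(self, geom, central_circles):
        pair = confusion_pair("protan", 20.0, display=geom.display)
        _, img1 = render_plate(pair, circles=central_circles, rng_seed=9, geom=geom)
        _, img2 = render_plate(pair, circles=central_circles, rng_seed=9, geom=geom)
        assert np.array_equal(img1, img2)

    def test_field_outside_circles_is_neutral_gray(self, geom, central_circles):
        pair = confusion_pair("protan", 60.0, display=geom.display)
        plate, img = render_plate(pair, circles=central_circles, rng_seed=2, geom=geom)
        corner = img[2, 2]
        assert corner[0] == corner[1] == corner[2]


class TestIsHit:
    @pytest.fixture()
    def plate(self, geom):
        pair = confusion_pair("deutan", 20.0, display=geom.display)
        return make_plate(pair, 3, geom)

    def test_exact_center(self, geom, plate):
        assert is_hit(plate.arrowhead_center_deg, plate, geom)

    def test_boundary_inclusive(self, geom, plate):
        hx, hy = plate.arrowhead_center_deg
        tx = geom.cm_to_deg(geom.deg_to_cm(hx) + 0.774)
        assert is_hit((tx, hy), plate, geom)

    def test_outside_radius(self, geom, plate):
        hx, hy = plate.arrowhead_center_deg
        tx = geom.cm_to_deg(geom.deg_to_cm(hx) + 0.80)
        assert not is_hit((tx, hy), plate, geom)

    def test_no_touch_is_never_a_hit(self, geom, plate):
        assert not is_hit(None, plate, geom)


class TestCatchPlate:
    def test_high_contrast_and_flag(self, geom):
        plate = make_catch_plate(1, geom)
        assert plate.is_catch_trial
        de = delta_e(
            rgb_to_lab(plate.color_pair.arrow_rgb, geom.display),
            rgb_to_lab(plate.color_pair.background_rgb, geom.display),
        )
        assert de >= 60.0

    def test_normal_observer_passes_catches(self, geom):
        from chromathresh.observer_sim import preset_observer, respond

        obs = preset_observer("trichromat_mean")
        rng = np.random.default_rng(0)
        hits = 0
        n = 400
        for i in range(n):
            plate = make_catch_plate(rng, geom)
            touch = respond(obs, plate, rng, geom)
            hits += is_hit(touch, plate, geom)
        assert hits / n > 0.95
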