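"""Unit tests for the geometric primitives of head-angle estimation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gazerange.head_pose import (
    MarkerDetection,
    SearchRegion,
    derotate,
    estimate_roll,
    extrapolate_reference,
    match_template_region,
    pixels_to_angle,
    plan_search_regions,
    split_into_sections,
)


def det(mid, x, y, score=1.0):
    return MarkerDetection(marker_id=mid, x=x, y=y, score=score)


class TestRoll:
    @pytest.mark.parametrize(
        "p1, p2, expected",
        [
            ((100, 50), (200, 50), 0.0),
            ((0, 0), (100, 100), 45.0),
            ((50, 10), (150, 60), math.degrees(math.atan(0.5))),  # 26.565
        ],
    )
    def test_pair_slope(self, p1, p2, expected):
        theta = estimate_roll(det(1, *p1), det(2, *p2))
        assert theta == pytest.approx(expected, abs=1e-9)
        # order of the pair must not matter: x-sorting happens internally
        assert estimate_roll(det(2, *p2), det(1, *p1)) == pytest.approx(theta)

    def test_vertical_pair_is_degenerate(self):
        with pytest.raises(ValueError, match="same x"):
            estimate_roll(det(1, 100, 0), det(2, 100, 50))

    def test_result_within_open_interval(self):
        theta = estimate_roll(det(1, 0, 0), det(2, 1, 10_000))
        assert -90.0 < theta < 90.0


class TestDerotate:
    def test_zero_angle_is_identity(self):
        assert derotate(3.5, -7.25, 0.0) == (3.5, -7.25)

    def test_quarter_turn(self):
        x, y = derotate(1.0, 0.0, 90.0)
        assert (x, y) == pytest.approx((0.0, 1.0), abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(
        x=st.floats(-1e3, 1e3),
        y=st.floats(-1e3, 1e3),
        theta=st.floats(-180, 180),
    )
    def test_inverse_composition(self, x, y, theta):
        xr, yr = derotate(*derotate(x, y, theta), -theta)
        assert (xr, yr) == pytest.approx((x, y), abs=1e-9)


class TestPixelsToAngle:
    def test_zero_displacement(self):
        assert pixels_to_angle(0.0, 640, 60.0) == 0.0

    def test_exact_proportionality(self):
        assert pixels_to_angle(64, 640, 60.0) == pytest.approx(6.0)

    @settings(derandomize=True, max_examples=50)
    @given(a=st.floats(-500, 500), b=st.floats(-500, 500))
    def test_linearity(self, a, b):
        f = lambda d: pixels_to_angle(d, 640, 60.0)
        assert f(a + b) == pytest.approx(f(a) + f(b), abs=1e-9)

    def test_invalid_camera_axis(self):
        with pytest.raises(ValueError):
            pixels_to_angle(10, 0, 60.0)
        with pytest.raises(ValueError):
            pixels_to_angle(10, 640, 180.0)


class TestReferenceExtrapolation:
    @pytest.mark.parametrize(
        "alpha, beta, ax, bx, expected",
        [
            (1.0, 1.0, 300.0, 200.0, 100.0),  # equal spacing -> symmetric
            (2.0, 1.0, 300.0, 200.0, 150.0),
        ],
    )
    def test_known_cases(self, alpha, beta, ax, bx, expected):
        assert extrapolate_reference(ax, bx, alpha, beta) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=200)
    @given(
        alpha=st.floats(0.1, 5.0),
        beta=st.floats(0.1, 5.0),
        bx=st.floats(-500, 500),
        gap=st.floats(1.0, 400.0),
    )
    def test_ratio_point_identity(self, alpha, beta, bx, gap):
        """B must be the alpha:beta ratio point of A and the extrapolated C."""
        ax = bx + gap  # Ax > Bx
        cx = extrapolate_reference(ax, bx, alpha, beta)
        assert (beta * ax + alpha * cx) / (alpha + beta) == pytest.approx(bx, abs=1e-9)
        assert cx < bx < ax

    def test_rejects_nonpositive_ratio(self):
        with pytest.raises(ValueError):
            extrapolate_reference(300, 200, 0.0, 1.0)


class TestSections:
    def test_exact_thirds_with_unit_template(self):
        bands = split_into_sections(SearchRegion(0, 0, 50, 300), template_height=1)
        spans = [(b.y0, b.y1) for b in bands]
        assert spans == [(100, 200), (0, 100), (200, 300)]  # center, upper, bottom

    def test_vertical_expansion(self):
        bands = split_into_sections(SearchRegion(0, 0, 50, 300), template_height=21)
        center = bands[0]
        assert (center.y0, center.y1) == (80, 220)  # 100 +/- (21 - 1)

    def test_bands_clip_to_region(self):
        region = SearchRegion(10, 40, 90, 340)
        for band in split_into_sections(region, template_height=25):
            assert band.y0 >= region.y0 and band.y1 <= region.y1
            assert (band.x0, band.x1) == (region.x0, region.x1)

    def test_straddling_marker_found_only_with_expansion(self):
        """A template crossing the 1/3 cut is missed by unexpanded bands."""
        tpl = np.zeros((20, 20))
        tpl[5:15, 5:15] = 255.0
        frame = np.full((300, 100), 10.0)
        y_anchor = 92  # spans rows 92..112, straddling the cut at 100
        frame[y_anchor : y_anchor + 20, 40:60] = tpl
        region = SearchRegion(0, 0, 100, 300)

        expanded = split_into_sections(region, template_height=20)
        hits = [
            match_template_region(frame, tpl, band, 0.99)
            for band in expanded
            if band.height >= 20
        ]
        assert any(h is not None and h.y == y_anchor for h in hits)

        naive = [
            SearchRegion(0, 0, 100, 100),
            SearchRegion(0, 100, 100, 200),
            SearchRegion(0, 200, 100, 300),
        ]
        naive_hits = [
            match_template_region(frame, tpl, band, 0.99) for band in naive
        ]
        assert all(h is None for h in naive_hits)


class TestMatchTemplate:
    def test_exact_copy_scores_one(self, rng):
        tpl = rng.uniform(0, 255, (17, 23))
        frame = np.full((200, 320), 128.0)
        frame[40:57, 120:143] = tpl
        d = match_template_region(
            frame, tpl, SearchRegion(0, 0, 320, 200), threshold=0.9
        )
        assert d is not None
        assert (d.x, d.y) == (120, 40)
        assert d.score == pytest.approx(1.0, abs=1e-6)

    def test_uniform_frame_yields_none(self, rng):
        tpl = rng.uniform(0, 255, (15, 15))
        frame = np.full((100, 100), 77.0)
        assert (
            match_template_region(frame, tpl, SearchRegion(0, 0, 100, 100), 0.5)
            is None
        )

    def test_template_larger_than_region_rejected(self, rng):
        tpl = rng.uniform(0, 255, (30, 30))
        frame = np.zeros((100, 100))
        with pytest.raises(ValueError, match="larger"):
            match_template_region(frame, tpl, SearchRegion(0, 0, 20, 20), 0.5)

    def test_noise_background_detection_within_one_pixel(self, rng):
        tpl = rng.uniform(0, 255, (15, 15))
        frame = rng.normal(128, 30, (120, 160)).clip(0, 255)
        frame[60:75, 90:105] = tpl
        d = match_template_region(frame, tpl, SearchRegion(0, 0, 160, 120), 0.7)
        assert d is not None
        assert abs(d.x - 90) <= 1 and abs(d.y - 60) <= 1


class TestSearchPlanner:
    @pytest.fixture()
    def tpls(self, templates):
        return templates

    def test_cold_start_full_frame_for_first_marker(self, tpls):
        regions = plan_search_regions(None, None, (480, 640), tpls)
        assert regions[1] == [SearchRegion(0, 0, 640, 480)]
        # with no priors, every marker may be anywhere
        for mid in (2, 3, 4):
            assert regions[mid] == [SearchRegion(0, 0, 640, 480)]

    def test_outermost_marker_excluded_when_inner_markers_present(self, tpls):
        prev = {1: det(1, 50, 200), 2: det(2, 250, 200)}
        regions = plan_search_regions(prev, None, (480, 640), tpls)
        assert regions[4] == []

    def test_ordering_constraint_without_motion(self, tpls):
        prev = {2: det(2, 300, 200)}
        regions = plan_search_regions(prev, {2: det(2, 300, 200)}, (480, 640), tpls)
        for r in regions[3]:
            assert r.x0 > 300

    def test_motion_extends_region_along_displacement(self, tpls):
        gain = 1.5
        prev2 = {1: det(1, 100, 200)}
        prev = {1: det(1, 140, 200)}  # moved +40 px in x
        static = plan_search_regions(
            {1: det(1, 140, 200)}, {1: det(1, 140, 200)}, (480, 640), tpls,
            extension_gain=gain,
        )[1][0]
        moving = plan_search_regions(
            prev, prev2, (480, 640), tpls, extension_gain=gain
        )[1][0]
        assert moving.x1 == static.x1 + gain * 40
        assert moving.x0 == static.x0  # no extension against the motion

    def test_regions_stay_inside_frame(self, tpls):
        prev = {1: det(1, 5, 5), 4: det(4, 630, 470)}
        regions = plan_search_regions(prev, prev, (480, 640), tpls)
        for rs in regions.values():
            for r in rs:
                assert 0 <= r.x0 < r.x1 <= 640
                assert 0 <= r.y0 < r.y1 <= 480
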