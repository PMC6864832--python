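"""Histogram, Gaussian fit and threshold-span gaze-range statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from gazerange.gaze_range import (
    FIVE_PERCENT_SIGMA,
    EmptySessionError,
    build_histogram,
    compare_subjects,
    fit_gaussian,
    gaze_range,
    range_from_threshold,
)


def gauss_samples(rng, n, mu=(0.0, 0.0), sigma=(15.0, 8.0)):
    return np.column_stack(
        [rng.normal(mu[0], sigma[0], n), rng.normal(mu[1], sigma[1], n)]
    )


class TestHistogram:
    def test_point_mass_single_bin(self):
        samples = np.tile([[7.0, -3.0]], (10, 1))
        h = build_histogram(samples, bin_width=5.0)
        assert h.counts.shape == (1, 1)
        assert h.counts[0, 0] == 10
        assert h.n_samples == 10

    def test_boundary_sample_falls_in_upper_bin(self):
        h = build_histogram(np.array([[5.0, 0.0], [4.999, 0.0]]), bin_width=5.0)
        assert h.counts.shape == (2, 1)
        assert list(h.marginal("x")) == [1, 1]
        assert h.x_edges[1] == 5.0

    def test_counts_match_naive_binning(self, rng):
        samples = gauss_samples(rng, 1000)
        bw = 4.0
        h = build_histogram(samples, bin_width=bw)
        # brute-force per-sample assignment
        for x, y in samples[:200]:
            ix = int(np.searchsorted(h.x_edges, x, side="right")) - 1
            iy = int(np.searchsorted(h.y_edges, y, side="right")) - 1
            assert h.x_edges[ix] <= x < h.x_edges[ix + 1]
            assert h.counts[ix, iy] >= 1
        naive = np.zeros_like(h.counts)
        for x, y in samples:
            naive[int(x // bw) - int(h.x_edges[0] // bw), int(y // bw) - int(h.y_edges[0] // bw)] += 1
        np.testing.assert_array_equal(h.counts, naive)

    def test_marginals_conserve_sample_count(self, rng):
        samples = gauss_samples(rng, 777)
        h = build_histogram(samples, bin_width=3.0)
        assert h.marginal("x").sum() == 777
        assert h.marginal("y").sum() == 777

    def test_invalid_samples_excluded(self):
        df = pd.DataFrame(
            {"x_gaze": [0.0, math.nan, 1.0], "y_gaze": [0.0, 0.0, 1.0],
             "valid": [True, True, False]}
        )
        assert build_histogram(df).n_samples == 1

    def test_empty_session_raises(self):
        df = pd.DataFrame({"x_gaze": [], "y_gaze": [], "valid": []})
        with pytest.raises(EmptySessionError):
            build_histogram(df)


class TestGaussianFit:
    def test_parameter_recovery(self, rng):
        samples = gauss_samples(rng, 10_000, mu=(5.0, -2.0), sigma=(10.0, 6.0))
        fit = fit_gaussian(samples)
        assert fit.mu_x == pytest.approx(5.0, abs=0.3)
        assert fit.sigma_x == pytest.approx(10.0, abs=0.3)
        assert fit.mu_y == pytest.approx(-2.0, abs=0.3)
        assert fit.sigma_y == pytest.approx(6.0, abs=0.3)

    def test_mirrored_samples_center_at_zero(self):
        samples = np.array([[-3.0, -1.0], [3.0, 1.0], [0.0, 0.0]])
        fit = fit_gaussian(samples)
        assert fit.mu_x == pytest.approx(0.0, abs=1e-12)
        assert fit.mu_y == pytest.approx(0.0, abs=1e-12)

    def test_interval_width_is_392_sigma(self, rng):
        samples = gauss_samples(rng, 500)
        fit = fit_gaussian(samples)
        lo, hi = fit.interval95("x")
        assert hi - lo == pytest.approx(2 * 1.959964 * fit.sigma_x, rel=1e-4)

    def test_zero_variance_is_degenerate(self):
        samples = np.tile([[1.0, 2.0]], (5, 1))
        with pytest.raises((ValueError, EmptySessionError)):
            fit_gaussian(samples)


class TestThresholdRange:
    def test_point_mass_spans_one_bin(self):
        samples = np.tile([[7.0, -3.0]], (10, 1))
        r = gaze_range(samples, bin_width=5.0)
        assert r.x_span == 5.0
        assert r.y_span == 5.0
        assert r.area == 25.0

    def test_gaussian_closed_form(self, rng):
        """The marginal of a Gaussian drops to 5% of its peak at
        sqrt(2 ln 20) = 2.448 sigma, so the span converges to 4.90 sigma."""
        sigma = 10.0
        samples = np.column_stack(
            [rng.normal(0, sigma, 50_000), rng.normal(0, sigma, 50_000)]
        )
        r = gaze_range(samples, bin_width=2.0, threshold=0.05)
        expected = 2 * FIVE_PERCENT_SIGMA * sigma  # 48.95 deg
        assert r.x_span == pytest.approx(expected, rel=0.10)
        assert r.y_span == pytest.approx(expected, rel=0.10)

    def test_count_scale_invariance(self, rng):
        samples = gauss_samples(rng, 2000)
        h = build_histogram(samples, 5.0)
        doubled = type(h)(
            bin_width=h.bin_width, x_edges=h.x_edges, y_edges=h.y_edges,
            counts=h.counts * 2,
        )
        a, b = range_from_threshold(h), range_from_threshold(doubled)
        assert (a.x_min, a.x_max, a.y_min, a.y_max) == (
            b.x_min, b.x_max, b.y_min, b.y_max)

    def test_lower_threshold_never_shrinks_range(self, rng):
        samples = gauss_samples(rng, 3000)
        h = build_histogram(samples, 5.0)
        spans = [
            range_from_threshold(h, th) for th in (0.5, 0.2, 0.1, 0.05, 0.01)
        ]
        for tight, loose in zip(spans, spans[1:]):
            assert loose.x_span >= tight.x_span
            assert loose.y_span >= tight.y_span
            assert loose.area >= tight.area

    def test_area_is_product_of_spans(self, rng):
        r = gaze_range(gauss_samples(rng, 1000))
        assert r.area == r.x_span * r.y_span

    def test_threshold_out_of_range(self, rng):
        h = build_histogram(gauss_samples(rng, 10), 5.0)
        with pytest.raises(ValueError):
            range_from_threshold(h, 0.0)


class TestCompareSubjects:
    def test_identical_sessions_ratio_one(self, rng):
        samples = gauss_samples(rng, 2000)
        r = gaze_range(samples)
        table = compare_subjects({"instructor": r, "subject_a": r})
        assert table.area_ratio.tolist() == [1.0, 1.0]
        assert not table.narrow.any()

    def test_halved_sigma_quarters_area(self, rng):
        wide = gaze_range(gauss_samples(rng, 20_000, sigma=(16.0, 16.0)), bin_width=2.0)
        narrow = gaze_range(gauss_samples(rng, 20_000, sigma=(8.0, 8.0)), bin_width=2.0)
        table = compare_subjects({"instructor": wide, "subject_b": narrow})
        ratio = table.set_index("subject").loc["subject_b", "area_ratio"]
        assert ratio == pytest.approx(0.25, rel=0.2)
        assert table.set_index("subject").loc["subject_b", "narrow"]

    def test_order_invariance(self, rng):
        a = gaze_range(gauss_samples(rng, 3000, sigma=(15.0, 8.0)))
        b = gaze_range(gauss_samples(rng, 3000, sigma=(10.0, 6.0)))
        c = gaze_range(gauss_samples(rng, 3000, sigma=(20.0, 10.0)))
        t1 = compare_subjects({"ref": a, "s1": b, "s2": c}, reference="ref")
        t2 = compare_subjects({"s2": c, "s1": b, "ref": a}, reference="ref")
        pd.testing.assert_frame_equal(t1, t2)

    def test_duplicate_names_rejected(self, rng):
        r = gaze_range(gauss_samples(rng, 100))
        with pytest.raises(ValueError, match="duplicate"):
            compare_subjects([("a", r), ("a", r)])

    def test_fewer_than_two_subjects_rejected(self, rng):
        r = gaze_range(gauss_samples(rng, 100))
        with pytest.raises(ValueError):
            compare_subjects({"a": r})
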