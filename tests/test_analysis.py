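"""Trace analytics: FFT amplitude ratio, Pearson correlation, decay fits,
and kymograph patch lifetimes, validated against analytic constructions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from podowave import (
    amplitude_ratio,
    correlation_vs_distance,
    pattern_lifetime,
    pearson,
)
from podowave.cluster import Kymograph
from podowave.fixtures import FixtureSpec, make_fixture


class TestAmplitudeRatio:
    def test_constant_trace_has_zero_ratio(self):
        res = amplitude_ratio(np.full(128, 7.0), 15.0)
        assert res.ratio == 0.0

    def test_integer_period_sinusoid_analytic(self):
        # x(t) = 100 + 20 sin(2*pi*t/400), 15-s sampling over 6000 s:
        # the DFT has a single non-DC peak of amplitude 20, so the top-4
        # mean is 20/4 and the ratio 20/(4*100) = 0.05
        fx = make_fixture(
            FixtureSpec(kind="sinusoid-trace", period=400.0, mean=100.0,
                        amplitude=20.0, duration=6000.0)
        )
        t, x = fx.data
        res = amplitude_ratio(x, 15.0)
        assert res.dominant_period == pytest.approx(400.0, rel=1e-12)
        assert res.ratio == pytest.approx(fx.truth["amplitude_ratio"], rel=1e-9)
        assert res.amplitudes[0] == pytest.approx(20.0, rel=1e-9)
        assert np.all(res.amplitudes[1:] < 1e-9)

    def test_offset_changes_ratio_only_through_the_mean(self):
        rng = np.random.default_rng(8)
        x = 50.0 + 5.0 * np.sin(2 * np.pi * np.arange(256) / 32) + rng.normal(0, 0.5, 256)
        c = 30.0
        r0 = amplitude_ratio(x, 1.0)
        r1 = amplitude_ratio(x + c, 1.0)
        assert r1.ratio == pytest.approx(r0.ratio * x.mean() / (x.mean() + c), rel=1e-9)

    def test_rejects_short_and_nan_traces(self):
        with pytest.raises(ValueError):
            amplitude_ratio(np.ones(32), 15.0)
        bad = np.ones(128)
        bad[3] = np.nan
        with pytest.raises(ValueError):
            amplitude_ratio(bad, 15.0)


class TestPearson:
    def test_self_correlation_is_one(self, rng):
        a = rng.standard_normal(100)
        assert pearson(a, a) == pytest.approx(1.0, abs=1e-12)

    def test_negated_shifted_is_minus_one(self, rng):
        a = rng.standard_normal(100)
        assert pearson(a, -a + 3.0) == pytest.approx(-1.0, abs=1e-12)

    def test_quadrature_sinusoids_are_uncorrelated(self):
        # direct-summation orthogonality over exactly 10 full periods
        n = 500
        t = np.arange(n) / n * 10 * 2 * math.pi
        assert abs(pearson(np.sin(t), np.cos(t))) < 1e-10

    @given(
        slope=st.floats(0.1, 50.0),
        offset=st.floats(-100.0, 100.0),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_positive_affine_maps(self, slope, offset, seed):
        r = np.random.default_rng(seed)
        a, b = r.standard_normal(50), r.standard_normal(50)
        assert abs(pearson(slope * a + offset, b) - pearson(a, b)) < 1e-12

    def test_degenerate_series_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            pearson(np.ones(10), np.arange(10.0))

    def test_matches_numpy_corrcoef(self, rng):
        a, b = rng.standard_normal(64), rng.standard_normal(64)
        assert pearson(a, b) == pytest.approx(np.corrcoef(a, b)[0, 1], abs=1e-12)


class TestCorrelationVsDistance:
    def test_identical_traces_flagged_infinite_length(self, rng):
        base = rng.standard_normal(120)
        traces = np.tile(base, (12, 1))
        pos = rng.uniform(0, 10, (12, 2))
        curve = correlation_vs_distance(traces, pos)
        assert curve.xi_flagged
        assert math.isinf(curve.xi)
        assert np.nanmax(np.abs(curve.mean_rho - 1.0)) < 1e-9

    def test_plane_wave_recovers_wavelength(self):
        fx = make_fixture(
            FixtureSpec(kind="plane-wave-field", q=0.333, n_positions=40,
                        extent=30.0, duration=6000.0, seed=3)
        )
        traces, pos = fx.data
        curve = correlation_vs_distance(traces, pos, bin_width=0.5)
        assert curve.lambda_f == pytest.approx(fx.truth["wavelength"], rel=0.05)

    def test_white_noise_has_no_spatial_structure(self):
        fx = make_fixture(
            FixtureSpec(kind="white-noise-traces", n_traces=40, duration=3000.0, seed=5)
        )
        traces, pos = fx.data
        curve = correlation_vs_distance(traces, pos, bin_width=1.0)
        ok = curve.n_pairs >= 5
        bound = 2.0 / np.sqrt(curve.n_pairs[ok])
        assert np.all(np.abs(curve.mean_rho[ok]) < bound + 0.05)

    def test_needs_enough_traces(self, rng):
        with pytest.raises(ValueError):
            correlation_vs_distance(
                rng.standard_normal((4, 100)), rng.uniform(0, 5, (4, 2))
            )


class TestPatternLifetime:
    def _kymo(self, data):
        return Kymograph(
            data=data,
            positions=0.5 * np.arange(data.shape[0]),
            frame_interval=15.0,
            pixel_size=0.5,
            rect=(0, 10, 0, 2),
        )

    def test_static_field_has_no_patches(self):
        kym = self._kymo(np.full((20, 50), 0.7))
        with pytest.raises(ValueError, match="patches"):
            pattern_lifetime(kym, 0.7)

    def test_standing_sinusoid_patch_duration(self):
        """A standing oscillation of amplitude A exceeds the (1+thr) line
        for the analytically known fraction of each period."""
        steady, A, T = 0.7, 0.14, 400.0
        thr = 0.05
        ts = 15.0 * np.arange(160)
        xs = 0.5 * np.arange(30)
        data = steady + A * np.outer(np.ones_like(xs), np.sin(2 * np.pi * ts / T))
        kym = self._kymo(data)
        # fraction of a period above threshold: acos crossing of A sin = thr*steady
        frac = 1.0 - 2 * math.asin(thr * steady / A) / math.pi
        expected_min = frac * (T / 2) / 60.0
        got = pattern_lifetime(kym, steady)
        assert got == pytest.approx(expected_min, rel=0.15)

    def test_travelling_wave_patches_outlive_standing_ones(self):
        steady, A, T, q = 0.7, 0.14, 400.0, 2 * np.pi / 6.0
        ts = 15.0 * np.arange(160)
        xs = 0.5 * np.arange(30)
        standing = steady + A * np.outer(np.ones_like(xs), np.sin(2 * np.pi * ts / T))
        travelling = steady + A * np.sin(
            q * xs[:, None] - 2 * np.pi * ts[None, :] / T
        )
        lt_stand = pattern_lifetime(self._kymo(standing), steady)
        lt_trav = pattern_lifetime(self._kymo(travelling), steady)
        # a travelling crest stays above threshold somewhere in the window
        assert lt_trav > lt_stand
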