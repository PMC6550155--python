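"""Smoothed-derivative engine, summary stats, peaks, and vector assembly."""

import math

import numpy as np
import pytest

import graphokin as gk
from graphokin.dynamics_features import (FEATURE_NAMES, DerivedSeries,
                                         DynamicsConfig, acceleration_stats,
                                         channel_change_speed, derived_speed,
                                         extract_cohort, extract_features,
                                         in_air_time_ratio, peaks_per_second,
                                         series_stats, slope_over_time)
from graphokin.spectral import InsufficientDataError

from conftest import make_recording


def make_series(t, v, rate=20.0, duration=None):
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    return DerivedSeries(t=t, v=v, seg=np.zeros(len(v)), effective_rate=rate,
                         on_surface_duration=duration or float(t[-1] - t[0]))


class TestDerivedSpeed:
    def test_uniform_motion_recovers_speed(self):
        n = 2000
        t = np.arange(n) / 200.0
        rec = make_recording(t=t, x=100.0 * t, y=np.zeros(n))
        s = derived_speed(rec)
        stats = series_stats(s)
        assert stats["mean"] == pytest.approx(100.0, rel=5e-3)
        assert stats["std"] < 1e-6 * stats["mean"]

    def test_stationary_pen_zero_speed(self):
        rec = make_recording(n=500, x=np.full(500, 3.0), y=np.full(500, 4.0))
        assert np.allclose(derived_speed(rec).v, 0.0)

    def test_circle_speed_matches_analytic(self):
        rate, r, omega = 200.0, 100.0, 2 * np.pi * 0.5
        t = np.arange(4000) / rate
        rec = make_recording(t=t, x=r * np.cos(omega * t), y=r * np.sin(omega * t))
        s = derived_speed(rec)
        assert s.v.mean() == pytest.approx(r * omega, rel=0.01)

    def test_smoothing_bias_vanishes_as_window_shrinks(self):
        rate, r, omega = 200.0, 50.0, 2 * np.pi * 1.0
        t = np.arange(2000) / rate
        rec = make_recording(t=t, x=r * np.cos(omega * t), y=r * np.sin(omega * t))
        errs = []
        for n in (20, 10, 2, 1):
            s = derived_speed(rec, DynamicsConfig(smooth_n=n, subsample=1))
            errs.append(abs(s.v.mean() - r * omega))
        assert errs[0] > errs[-1]
        assert errs[-1] / (r * omega) < 2e-4

    def test_measurements_never_straddle_pen_lifts(self):
        n = 400
        on = np.ones(n, bool)
        on[180:220] = False
        t = np.arange(n) / 200.0
        # teleport the pen while in the air: straddling would show a speed spike
        x = np.where(np.arange(n) < 200, np.arange(n) * 1.0, 1e5 + np.arange(n) * 1.0)
        rec = make_recording(t=t, x=x, y=np.zeros(n), on_surface=on)
        s = derived_speed(rec)
        assert s.v.max() < 300.0

    def test_too_short_strokes_raise(self):
        rec = make_recording(n=8)
        with pytest.raises(InsufficientDataError):
            derived_speed(rec, DynamicsConfig(smooth_n=10))


class TestChannelChangeSpeed:
    def test_constant_pressure_zero(self):
        rec = make_recording(n=500, pressure=np.full(500, 0.7))
        assert np.allclose(channel_change_speed(rec, "pressure").v, 0.0)

    def test_linear_ramp_rate_recovered(self):
        n = 2000
        t = np.arange(n) / 200.0
        rec = make_recording(t=t, pressure=np.clip(0.01 * t, 0, 1))
        s = channel_change_speed(rec, "pressure")
        np.testing.assert_allclose(s.v, 0.01, rtol=1e-6)

    def test_tilt_sinusoid_matches_numeric_oracle(self):
        n = 4000
        t = np.arange(n) / 200.0
        tilt = 10.0 * np.sin(2 * np.pi * 0.5 * t)
        rec = make_recording(t=t, tilt_y=tilt)
        cfg = DynamicsConfig()
        s = channel_change_speed(rec, "tilt_y", cfg)
        # oracle: same moving-average + subsample pipeline, independent code
        kernel = np.ones(cfg.smooth_n) / cfg.smooth_n
        sm = np.convolve(tilt, kernel, "valid")[::cfg.subsample]
        st = np.convolve(t, kernel, "valid")[::cfg.subsample]
        expected = np.abs(np.diff(sm)) / np.diff(st)
        assert s.v.mean() == pytest.approx(expected.mean(), rel=0.01)

    def test_unknown_channel_rejected(self):
        rec = make_recording(n=100)
        with pytest.raises(ValueError):
            channel_change_speed(rec, "altitude")


class TestSeriesSummaries:
    @pytest.mark.parametrize("values,expected", [
        ([2, 2, 2], (2.0, 2.0, 0.0)),
        ([0, 4], (2.0, 4.0, 2.0)),
    ])
    def test_stats_examples(self, values, expected):
        out = series_stats(np.array(values, dtype=float))
        assert (out["mean"], out["max"], out["std"]) == expected

    def test_stats_match_formula_oracle(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=500)
        out = series_stats(v)
        assert out["mean"] == pytest.approx(sum(v) / len(v))
        assert out["std"] == pytest.approx(math.sqrt(sum((x - out["mean"]) ** 2
                                                         for x in v) / len(v)))

    def test_slope_examples(self):
        t = np.linspace(0, 10, 50)
        assert slope_over_time(make_series(t, np.full(50, 5.0))) == pytest.approx(0.0)
        assert slope_over_time(make_series(t, 3.0 * t)) == pytest.approx(3.0)

    def test_noisy_slope_within_ci(self):
        rng = np.random.default_rng(1)
        t = np.linspace(0, 100, 400)
        v = 2.0 * t + rng.normal(0, 5.0, len(t))
        se = 5.0 / math.sqrt(np.sum((t - t.mean()) ** 2))
        assert abs(slope_over_time(make_series(t, v)) - 2.0) < 4 * se


class TestPeaksPerSecond:
    def test_monotone_series_no_peaks(self):
        t = np.linspace(0, 5, 100)
        assert peaks_per_second(make_series(t, t ** 2)) == 0.0

    def test_two_hz_sinusoid_gives_four_per_second(self):
        t = np.arange(0, 5, 1 / 20.0)
        v = np.sin(2 * np.pi * 2.0 * t)
        cfg = DynamicsConfig(peak_sigma=0.02)  # well below the 0.5-s period
        rate = peaks_per_second(make_series(t, v, duration=5.0), cfg)
        assert rate == pytest.approx(4.0)

    def test_smoothing_never_adds_extrema(self):
        rng = np.random.default_rng(2)
        t = np.arange(0, 20, 1 / 20.0)
        v = rng.normal(size=len(t))
        counts = [peaks_per_second(make_series(t, v, duration=20.0),
                                   DynamicsConfig(peak_sigma=sig))
                  for sig in (0.05, 0.1, 0.25, 0.5, 1.0)]
        assert all(b <= a for a, b in zip(counts, counts[1:]))


class TestAcceleration:
    def test_constant_speed_zero_acceleration(self):
        t = np.linspace(0, 10, 200)
        out = acceleration_stats(make_series(t, np.full(200, 7.0)))
        assert (out["mean"], out["max"], out["std"]) == (0.0, 0.0, 0.0)

    def test_linear_speed_gives_slope(self):
        t = np.linspace(0, 10, 200)
        out = acceleration_stats(make_series(t, 2.5 * t))
        assert out["mean"] == pytest.approx(2.5)
        assert out["std"] == pytest.approx(0.0, abs=1e-9)

    def test_matches_differentiation_oracle(self):
        rng = np.random.default_rng(3)
        t = np.cumsum(rng.uniform(0.01, 0.1, 300))
        v = np.cumsum(rng.normal(0, 1, 300))
        out = acceleration_stats(make_series(t, v))
        expected = np.abs(np.diff(v)) / np.diff(t)
        assert out["mean"] == pytest.approx(expected.mean())


class TestInAirRatio:
    def test_all_on_surface(self):
        assert in_air_time_ratio(make_recording(n=100)) == 0.0

    def test_alternating_seconds(self):
        t = np.arange(2000) / 200.0
        on = (t.astype(int) % 2) == 0  # 1 s on, 1 s off
        ratio = in_air_time_ratio(make_recording(t=t, on_surface=on))
        assert ratio == pytest.approx(0.5, abs=0.01)

    def test_matches_timestamp_sum_oracle(self):
        rng = np.random.default_rng(4)
        t = np.cumsum(rng.uniform(1e-3, 0.05, 500))
        on = rng.integers(0, 2, 500).astype(bool)
        rec = make_recording(t=t, on_surface=on)
        off = sum(b - a for a, b, o in zip(t, t[1:], on) if not o)
        assert in_air_time_ratio(rec) == (off / (t[-1] - t[0]))


class TestFeatureAssembly:
    def test_full_trace_has_no_missing_features(self, small_cohort):
        _, cohort, _ = small_cohort
        ref = cohort.reference()
        assert not cohort.features.isna().any().any()
        assert tuple(cohort.features.columns) == FEATURE_NAMES

    def test_extraction_is_deterministic(self, short_td_trace):
        a = extract_features(short_td_trace).to_series()
        b = extract_features(short_td_trace).to_series()
        assert a.equals(b)

    def test_truncated_recording_flags_missing_not_fatal(self, short_td_trace):
        rec = gk.truncate(short_td_trace, 5.0)
        fv = extract_features(rec)
        # very short recordings lose the long-packet spectral families only
        assert not math.isnan(fv.values["in_air_ratio"])
        assert not math.isnan(fv.values["speed_mean"])

    def test_unit_rescaling_coherence(self, short_td_trace):
        rec = short_td_trace
        c = 4.0
        scaled = rec.replace(x=c * rec.x, y=c * rec.y)
        a = extract_features(rec).values
        b = extract_features(scaled).values
        assert b["speed_mean"] == pytest.approx(c * a["speed_mean"], rel=1e-9)
        assert b["accel_mean"] == pytest.approx(c * a["accel_mean"], rel=1e-9)
        assert b["in_air_ratio"] == pytest.approx(a["in_air_ratio"], rel=1e-12)
        assert b["speed_peaks_per_s"] == pytest.approx(a["speed_peaks_per_s"])
        assert b["speed_freq_median"] == pytest.approx(a["speed_freq_median"])
        assert b["speed_freq_bandwidth"] == pytest.approx(a["speed_freq_bandwidth"])

    def test_rate_halving_leaves_features_comparable(self, short_td_trace):
        """Down-sampling the same trace to 100 Hz moves features only by
        discretization error: the in-air ratio is nearly exact, time-domain
        speed within the smoothing bias, the spectral median within a bin."""
        rec = short_td_trace
        half = rec.replace(t=rec.t[::2], x=rec.x[::2], y=rec.y[::2],
                           pressure=rec.pressure[::2], tilt_x=rec.tilt_x[::2],
                           tilt_y=rec.tilt_y[::2], on_surface=rec.on_surface[::2],
                           sampling_rate=rec.sampling_rate / 2)
        a = extract_features(rec).values
        b = extract_features(half).values
        assert abs(a["in_air_ratio"] - b["in_air_ratio"]) < 0.005
        assert b["speed_mean"] == pytest.approx(a["speed_mean"], rel=0.10)
        assert abs(a["speed_freq_median"] - b["speed_freq_median"]) < 0.5

    def test_cohort_reference_spectra_share_axes(self, small_cohort):
        _, cohort, _ = small_cohort
        ref = cohort.reference()
        for family, spec in ref.spectra.items():
            packet = cohort.packets[family]
            assert len(spec.freqs) == packet // 2 + 1
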