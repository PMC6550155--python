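"""Geometry features: segmentation, spacing, density, moment, size, tremor."""

import math

import numpy as np
import pytest

import graphokin as gk
from graphokin.spectral import InsufficientDataError
from graphokin.static_features import (StaticConfig, handwriting_density,
                                       handwriting_moment, handwriting_size,
                                       segment_lines, segment_words,
                                       space_between_words, tremor_signal,
                                       tremor_spectral_features)
from graphokin.trace_model import segment_strokes

from conftest import make_recording


def multi_stroke_recording(gaps, gap_time=0.5, rate=200.0, n=40):
    """Horizontal strokes separated by pen-up hops; ``gaps`` lists the x gap
    before each stroke after the first. One hover sample bridges each hop."""
    ts, xs, on = [], [], []
    t0, x0 = 0.0, 0.0
    for k, gap in enumerate([None] + list(gaps)):
        if gap is not None:
            ts.append(np.array([t0 + gap_time / 2.0]))
            xs.append(np.array([x0 + gap / 2.0]))
            on.append(np.array([False]))
            t0 += gap_time
            x0 += gap
        t = t0 + np.arange(n) / rate
        x = x0 + np.linspace(0.0, 100.0, n)
        ts.append(t)
        xs.append(x)
        on.append(np.ones(n, bool))
        t0 = t[-1] + 1.0 / rate
        x0 = x[-1]
    t, x, mask = np.concatenate(ts), np.concatenate(xs), np.concatenate(on)
    return make_recording(t=t, x=x, y=np.zeros(len(t)), on_surface=mask)


def two_stroke_recording(gap_time, gap_x, rate=200.0):
    return multi_stroke_recording([gap_x], gap_time=gap_time, rate=rate)


class TestSegmentation:
    def test_monotone_strokes_form_one_line(self):
        rec = two_stroke_recording(0.5, 60.0)
        lines = segment_lines(segment_strokes(rec))
        assert len(lines) == 1

    def test_x_reset_with_descent_starts_new_line(self):
        n = 50
        t = np.arange(2 * n) / 200.0
        x = np.concatenate([np.linspace(0, 800, n), np.linspace(0, 800, n)])
        y = np.concatenate([50 + 20 * np.sin(np.linspace(0, 6, n)),
                            450 + 20 * np.sin(np.linspace(0, 6, n))])
        rec = make_recording(t=t, x=x, y=y)
        lines = segment_lines(segment_strokes(rec))
        assert len(lines) == 1  # one stroke cannot split
        rec2 = make_recording(t=t, x=x, y=y,
                              on_surface=np.r_[np.ones(n), np.ones(n)].astype(bool))
        # split into two strokes via a pen-up sample in the middle
        on = np.ones(2 * n, bool)
        on[n - 1] = False
        rec2 = make_recording(t=t, x=x, y=y, on_surface=on)
        assert len(segment_lines(segment_strokes(rec2))) == 2

    def test_word_split_requires_both_thresholds(self):
        cfg = StaticConfig()
        both = two_stroke_recording(0.5, 60.0)
        words = segment_words(segment_lines(segment_strokes(both), cfg)[0], cfg)
        assert len(words) == 2
        close_x = two_stroke_recording(0.5, 10.0)
        words = segment_words(segment_lines(segment_strokes(close_x), cfg)[0], cfg)
        assert len(words) == 1
        quick = two_stroke_recording(0.05, 60.0)
        words = segment_words(segment_lines(segment_strokes(quick), cfg)[0], cfg)
        assert len(words) == 1

    def test_simulator_structure_recovered(self, td_profile):
        profile = td_profile.replace(duration=60.0, words_per_line=4)
        rec = gk.generate_trace(profile, seed=5)
        strokes = segment_strokes(rec)
        lines = segment_lines(strokes)
        words = [w for i, line in enumerate(lines)
                 for w in segment_words(line, line_index=i)]
        # the generator writes one stroke per word and four words per line
        assert len(words) == len(strokes)
        assert len(lines) == math.ceil(len(words) / profile.words_per_line)


class TestSpacing:
    def test_single_gap_closed_form(self):
        rec = two_stroke_recording(0.5, 50.0)
        out = space_between_words(rec)
        assert out["mean_log_gap"] == pytest.approx(math.log(50.0))
        assert out["gap_std"] == pytest.approx(0.0)

    def test_two_gaps_mean_and_std(self):
        rec = multi_stroke_recording([40.0, 60.0])
        # word_gap_x below both gaps so each pen-up hop is a word boundary
        out = space_between_words(rec, StaticConfig(word_gap_x=20.0))
        assert out["mean_log_gap"] == pytest.approx(math.log(50.0))
        assert out["gap_std"] == pytest.approx(10.0)

    def test_missing_when_single_word(self):
        rec = make_recording(n=50, x=np.linspace(0, 100, 50))
        out = space_between_words(rec)
        assert math.isnan(out["mean_log_gap"]) and math.isnan(out["gap_std"])

    def test_simulator_gap_recovery(self, td_profile):
        profile = td_profile.replace(duration=120.0, tremor_amplitude=0.0)
        rec = gk.generate_trace(profile, seed=11)
        out = space_between_words(rec)
        gaps_mean = math.exp(out["mean_log_gap"])
        assert abs(gaps_mean - profile.word_gap_mean) < 12.0


class TestDensity:
    def test_points_in_one_cell(self):
        rng = np.random.default_rng(0)
        rec = make_recording(n=900, x=rng.uniform(0, 299, 900), y=rng.uniform(0, 299, 900))
        assert handwriting_density(rec) == pytest.approx(900.0)

    def test_two_cells_average(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.uniform(0, 299, 450), rng.uniform(301, 599, 450)])
        rec = make_recording(n=900, x=x, y=rng.uniform(0, 299, 900))
        assert handwriting_density(rec) == pytest.approx(450.0)

    def test_matches_histogram_oracle(self):
        rng = np.random.default_rng(2)
        n = 3000
        x, y = rng.uniform(0, 2000, n), rng.uniform(0, 1500, n)
        rec = make_recording(n=n, x=x, y=y)
        side = StaticConfig().density_cell_side
        ix = np.floor((x - x.min()) / side).astype(int)
        iy = np.floor((y - y.min()) / side).astype(int)
        counts = {}
        for a, b in zip(ix, iy):
            counts[(a, b)] = counts.get((a, b), 0) + 1
        expected = np.mean(list(counts.values()))
        assert handwriting_density(rec) == pytest.approx(expected)


class TestMomentAndSize:
    def test_flat_line_zero_moment(self):
        rec = make_recording(n=900, x=np.linspace(0, 1000, 900), y=np.zeros(900))
        assert handwriting_moment(rec) == pytest.approx(0.0)

    def test_constant_drift_per_bin(self):
        n, d = 1200, 7.0
        y = np.repeat(np.arange(4) * d, 300)
        rec = make_recording(n=n, x=np.linspace(0, 500, n), y=y)
        assert handwriting_moment(rec) == pytest.approx(d)

    def test_moment_grows_with_slope(self, td_profile):
        vals = []
        for slope in (0.0, 0.05, 0.15):
            rec = gk.generate_trace(td_profile.replace(duration=30.0), seed=3)
            rec = rec.replace(y=rec.y + slope * rec.x)
            vals.append(handwriting_moment(rec))
        assert vals[0] < vals[1] < vals[2]

    def test_degenerate_bin_zero_area(self):
        rec = make_recording(n=300, x=np.full(300, 5.0), y=np.full(300, 9.0),
                             t=np.arange(300) / 200.0)
        assert handwriting_size(rec) == pytest.approx(0.0)

    def test_rectangle_hull_area(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 100, 300)
        y = rng.uniform(0, 50, 300)
        x[:2], y[:2] = [0, 100], [0, 50]  # pin the hull corners
        rec = make_recording(n=300, x=x, y=y)
        assert handwriting_size(rec) == pytest.approx(5000.0)


class TestTremorSignal:
    def test_collinear_points_all_zero(self):
        rec = make_recording(n=600, x=np.linspace(0, 3000, 600), y=np.zeros(600))
        np.testing.assert_allclose(tremor_signal(rec), 0.0, atol=1e-9)

    def test_zigzag_scales_linearly(self):
        n = 600
        x = np.arange(n) * 10.0
        zig = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
        rec_a = make_recording(n=n, x=x, y=3.0 * zig)
        rec_2a = make_recording(n=n, x=x, y=6.0 * zig)
        np.testing.assert_allclose(tremor_signal(rec_2a), 2.0 * tremor_signal(rec_a),
                                   rtol=1e-9)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(4)
        n = 500
        x = np.cumsum(rng.uniform(1, 3, n))
        y = rng.normal(0, 2, n)
        rec = make_recording(n=n, x=x, y=y)
        theta = 0.7
        xr = x * np.cos(theta) - y * np.sin(theta)
        yr = x * np.sin(theta) + y * np.cos(theta)
        rot = make_recording(n=n, x=xr, y=yr)
        np.testing.assert_allclose(tremor_signal(rot), tremor_signal(rec),
                                   rtol=1e-9, atol=1e-9)

    def test_translation_invariance_of_static_features(self, short_td_trace):
        rec = short_td_trace
        shifted = rec.replace(x=rec.x + 1234.5, y=rec.y - 987.0)
        assert handwriting_density(shifted) == pytest.approx(handwriting_density(rec))
        assert handwriting_moment(shifted) == pytest.approx(handwriting_moment(rec))
        assert handwriting_size(shifted) == pytest.approx(handwriting_size(rec))
        a, b = space_between_words(rec), space_between_words(shifted)
        assert a["mean_log_gap"] == pytest.approx(b["mean_log_gap"])
        np.testing.assert_allclose(tremor_signal(shifted), tremor_signal(rec),
                                   rtol=1e-9, atol=1e-9)

    def test_windows_do_not_straddle_strokes(self):
        # 15 on-surface points per stroke -> one 10-point window each, 5 skipped
        n = 45
        on = np.ones(n, bool)
        on[15] = False
        on[31] = False
        rec = make_recording(n=n, x=np.arange(n) * 5.0, y=np.zeros(n), on_surface=on)
        sig = tremor_signal(rec)
        # strokes of 15, 15, 13 points -> one 10-point window (9 values) each
        assert len(sig) == 27

    def test_insufficient_data_raises(self):
        rec = make_recording(n=5)
        with pytest.raises(InsufficientDataError):
            tremor_signal(rec)

    def test_tremor_injection_raises_signal_and_bandwidth(self, td_profile):
        """A smooth trace has a narrower tremor spectrum than a shaky one."""
        base = td_profile.replace(duration=60.0, tremor_amplitude=0.0)
        quiet = gk.generate_trace(base, seed=21)
        shaky = gk.generate_trace(base.replace(tremor_amplitude=3.0, tremor_freq=8.0),
                                  seed=21)
        f_quiet = tremor_spectral_features(quiet)
        f_shaky = tremor_spectral_features(shaky)
        assert np.mean(tremor_signal(shaky)) > np.mean(tremor_signal(quiet))
        assert f_shaky["bandwidth"] > f_quiet["bandwidth"]
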