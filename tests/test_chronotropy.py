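"""Beat detection, rate series, stretch responses, stiffness regression."""

import numpy as np
import pytest

from sanstretch.chronotropy import (
    StretchStep,
    average_repeats,
    br_series,
    find_beats,
    largest_abs_response,
    response_vs_stiffness,
    stretch_response,
    ResponseRecord,
)
from sanstretch.synthetic import BeatTrainParams, gen_beat_trace
from sanstretch.trace import Trace


class TestFindBeats:
    def test_noise_free_recovery(self):
        trace, true_times = gen_beat_trace(BeatTrainParams(baseline_bpm=400), 30.0)
        det = find_beats(trace, max_rate_bpm=600)
        assert abs(len(det) - len(true_times)) <= 1
        assert len(true_times) == pytest.approx(200, abs=1)
        np.testing.assert_allclose(det, true_times, atol=1.5 / trace.fs_hz)

    @pytest.mark.parametrize("bpm", [190, 250, 320, 410, 440])
    def test_count_error_at_most_one_across_rates(self, bpm):
        trace, true_times = gen_beat_trace(BeatTrainParams(baseline_bpm=bpm), 30.0)
        det = find_beats(trace, max_rate_bpm=600)
        assert abs(len(det) - len(true_times)) <= 1

    def test_flat_trace_yields_nothing(self):
        flat = Trace(np.arange(0, 1000.0), np.zeros(1000))
        assert len(find_beats(flat)) == 0

    def test_doubled_peak_counted_once(self):
        # two bumps 40 ms apart, well inside the 100 ms refractory window
        t = np.arange(0, 2000.0)
        v = np.zeros_like(t)
        for beat in (500.0, 1500.0):
            v += np.exp(-0.5 * ((t - beat) / 4.0) ** 2)
            v += 0.8 * np.exp(-0.5 * ((t - beat - 40.0) / 4.0) ** 2)
        det = find_beats(Trace(t, v), max_rate_bpm=600)
        assert len(det) == 2

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            find_beats(Trace(np.array([]), np.array([])))


class TestBRSeries:
    def test_uniform_intervals_constant_rate(self):
        times, br = br_series(np.arange(0, 3.0, 0.15))
        np.testing.assert_allclose(br, 400.0)

    def test_single_long_interval_dips(self):
        beats = np.array([0.0, 0.15, 0.30, 0.50, 0.65, 0.80])
        _, br = br_series(beats)
        np.testing.assert_allclose(br, [400, 400, 300, 400, 400])

    def test_duplicate_times_rejected(self):
        with pytest.raises(ValueError):
            br_series(np.array([0.0, 0.15, 0.15, 0.30]))

    def test_generator_step_profile(self):
        params = BeatTrainParams(baseline_bpm=400, step_bpm=40, window=(10.0, 20.0))
        _, true_times = gen_beat_trace(params, 30.0)
        t, br = br_series(true_times)
        inside = (t > 10.5) & (t < 20.0)
        outside = t < 9.5
        np.testing.assert_allclose(br[inside], 440.0, rtol=1e-9)
        np.testing.assert_allclose(br[outside], 400.0, rtol=1e-9)


class TestStretchResponse:
    STEP = StretchStep(strain=0.4, stretch_window=(20.0, 50.0), baseline_window=(10.0, 20.0))

    def test_ten_percent_step_recovered(self):
        params = BeatTrainParams(baseline_bpm=400, step_bpm=40, window=(20.0, 50.0))
        trace, _ = gen_beat_trace(params, 60.0)
        rec = stretch_response(find_beats(trace, max_rate_bpm=600), self.STEP)
        assert rec.delta_br_pct == pytest.approx(10.0, abs=0.5)

    def test_null_step_near_zero(self):
        params = BeatTrainParams(baseline_bpm=400, step_bpm=0, window=(20.0, 50.0))
        trace, _ = gen_beat_trace(params, 60.0)
        rec = stretch_response(find_beats(trace, max_rate_bpm=600), self.STEP)
        assert abs(rec.delta_br_pct) < 0.5

    def test_sign_preserved_for_negative_steps(self):
        params = BeatTrainParams(baseline_bpm=400, step_bpm=-48, window=(20.0, 50.0))
        trace, _ = gen_beat_trace(params, 60.0)
        rec = stretch_response(find_beats(trace, max_rate_bpm=600), self.STEP)
        assert rec.delta_br_pct == pytest.approx(-12.0, abs=0.6)

    def test_insufficient_beats_flagged(self):
        with pytest.raises(ValueError, match="baseline window"):
            stretch_response(np.arange(20.0, 50.0, 0.15), self.STEP)

    def test_repeats_averaged(self):
        recs = [
            ResponseRecord(strain=0.4, delta_br_pct=8.0, br_baseline_bpm=400),
            ResponseRecord(strain=0.4, delta_br_pct=12.0, br_baseline_bpm=404),
        ]
        merged = average_repeats(recs)
        assert len(merged) == 1
        assert merged[0].delta_br_pct == pytest.approx(10.0)
        assert merged[0].averaged_over_repeats


class TestLargestAbsResponse:
    def test_max_of_absolutes(self):
        recs = [
            ResponseRecord(0.1, +5.0, 400),
            ResponseRecord(0.2, -12.0, 400),
            ResponseRecord(0.3, +8.0, 400),
        ]
        value, strain = largest_abs_response(recs)
        assert value == 12.0 and strain == 0.2

    def test_single_negative_record(self):
        value, strain = largest_abs_response([ResponseRecord(0.3, -7.0, 400)])
        assert value == 7.0

    def test_tie_breaks_toward_lower_strain(self):
        recs = [ResponseRecord(0.4, -9.0, 400), ResponseRecord(0.2, +9.0, 400)]
        value, strain = largest_abs_response(recs)
        assert value == 9.0 and strain == 0.2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            largest_abs_response([])


class TestResponseVsStiffness:
    def test_perfect_line(self):
        betas = np.array([2.0, 4.0, 6.0, 8.0])
        res = response_vs_stiffness(zip(betas, -3.0 * betas + 40.0))
        assert res.slope == pytest.approx(-3.0)
        assert res.r == pytest.approx(-1.0)

    def test_permutation_destroys_correlation(self, rng):
        betas = np.linspace(2, 10, 12)
        y = -3.0 * betas + 40.0
        rs = []
        for _ in range(200):
            rs.append(response_vs_stiffness(zip(betas, rng.permutation(y))).r)
        assert abs(np.mean(rs)) < 0.1

    def test_two_pairs_rejected(self):
        with pytest.raises(ValueError):
            response_vs_stiffness([(2.0, 10.0), (4.0, 5.0)])

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            response_vs_stiffness([(3.0, 1.0), (3.0, 2.0), (3.0, 3.0)])


class TestBeatGenerator:
    def test_seed_determinism(self):
        p = BeatTrainParams(noise_sd=0.1, seed=6)
        a, ta = gen_beat_trace(p, 20.0)
        b, tb = gen_beat_trace(p, 20.0)
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(ta, tb)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            BeatTrainParams(noise_sd=-0.1)

    def test_instantaneous_rate_inside_window(self):
        params = BeatTrainParams(baseline_bpm=400, step_bpm=40, window=(5.0, 15.0))
        _, times = gen_beat_trace(params, 20.0)
        d = np.diff(times)
        mid = (times[1:] > 6.0) & (times[1:] < 15.0)
        np.testing.assert_allclose(60.0 / d[mid], 440.0, rtol=1e-9)
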