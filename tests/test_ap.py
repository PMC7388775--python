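"""AP feature extraction and stretch-current phase alignment."""

import numpy as np
import pytest

from sanstretch.ap import detect_cycles, features, features_per_cycle, phase_alignment
from sanstretch.synthetic import APShapeParams, gen_ap_train
from sanstretch.trace import Trace


class TestDetectCycles:
    def test_counts_all_generated_minima(self, ap_train):
        params, trace, truth = ap_train
        bounds = detect_cycles(trace)
        assert len(bounds) == params.n_cycles  # 10 minima -> 9 complete cycles

    def test_boundaries_match_ground_truth(self, ap_train):
        params, trace, truth = ap_train
        bounds = detect_cycles(trace)
        np.testing.assert_allclose(
            bounds, truth.mdp_time_ms.to_numpy(), atol=params.dt + 1e-9
        )

    def test_constant_trace_rejected(self):
        flat = Trace(np.arange(0, 100, 0.5), np.full(200, -60.0))
        with pytest.raises(ValueError, match="no oscillation"):
            detect_cycles(flat)


class TestFeatures:
    def test_br_from_cycle_length(self):
        params = APShapeParams(cycle_length=150.0, n_cycles=6)
        trace, _ = gen_ap_train(params)
        bounds = detect_cycles(trace)
        f = features(trace, (bounds[0], bounds[1]))
        assert f.br_bpm == pytest.approx(400.0, rel=0.002)

    def test_mouse_like_rate(self):
        # 147 ms cycle -> ~408 bpm
        params = APShapeParams(cycle_length=147.0, n_cycles=4)
        _, truth = gen_ap_train(params)
        assert truth.br_bpm.iloc[0] == pytest.approx(60000 / 147, rel=1e-12)
        assert truth.br_bpm.iloc[0] == pytest.approx(408, abs=1)

    def test_apd20_recovered_within_one_sample(self, ap_train):
        params, trace, truth = ap_train
        bounds = detect_cycles(trace)
        f = features(trace, (bounds[0], bounds[1]))
        assert f.apd20_ms == pytest.approx(truth.apd20_ms.iloc[0], abs=2 * params.dt)

    def test_mdp_peak_recovered(self, ap_train):
        params, trace, truth = ap_train
        bounds = detect_cycles(trace)
        f = features(trace, (bounds[0], bounds[1]))
        assert f.mdp_mv == pytest.approx(params.mdp, abs=0.05)
        assert f.peak_mv == pytest.approx(params.peak, abs=0.05)
        assert f.mdp_mv < f.peak_mv

    def test_dd_rate_matches_generator_truth(self, ap_train):
        params, trace, truth = ap_train
        bounds = detect_cycles(trace)
        f = features(trace, (bounds[0], bounds[1]))
        assert f.dd_rate_mv_per_s == pytest.approx(
            truth.dd_rate_mv_per_s.iloc[0], rel=0.02
        )

    def test_linear_dd_segment_slope(self):
        """A constructed linear diastolic ramp of 50 mV/s is measured as such."""
        dt = 0.1
        t_dd, t_up, t_rep = 100.0, 2.0, 30.0
        t = np.arange(0, t_dd + t_up + t_rep + dt, dt)
        v = np.empty_like(t)
        dd = t <= t_dd
        v[dd] = -60.0 + 0.05 * t[dd]  # 50 mV/s
        up = (t > t_dd) & (t <= t_dd + t_up)
        v[up] = -55.0 + (20.0 + 55.0) * (t[up] - t_dd) / t_up
        rep = t > t_dd + t_up
        v[rep] = 20.0 - (20.0 + 60.0) * (t[rep] - t_dd - t_up) / t_rep
        trace = Trace(t, v)
        f = features(trace, (t[0], t[-1]))
        assert f.dd_rate_mv_per_s == pytest.approx(50.0, rel=0.01)

    def test_recovery_across_waveform_family(self):
        """Generator parameters are recovered for varied shapes at dt <= 0.5 ms."""
        for dd, pl, cl in [(0.3, 0.05, 130), (0.5, 0.2, 160), (0.4, 0.3, 250)]:
            params = APShapeParams(
                cycle_length=cl, dd_fraction=dd, plateau_fraction=pl,
                n_cycles=4, dt=0.5,
            )
            trace, truth = gen_ap_train(params)
            bounds = detect_cycles(trace)
            f = features(trace, (bounds[0], bounds[1]))
            # align to the ground-truth cycle starting at the first detected
            # boundary (an edge-truncated first minimum may be discarded)
            row = truth.iloc[(truth.mdp_time_ms - bounds[0]).abs().argmin()]
            assert f.cycle_length_ms == pytest.approx(cl, abs=2 * params.dt)
            assert f.apd20_ms == pytest.approx(row.apd20_ms, abs=2 * params.dt)
            assert f.upstroke_time_ms == pytest.approx(
                row.upstroke_time_ms, abs=2 * params.dt
            )


class TestPhaseAlignment:
    def test_rising_ramp_fully_aiding(self):
        t = np.arange(0, 100.5, 0.5)
        trace = Trace(t, np.linspace(-60, -40, len(t)))
        seg = phase_alignment(trace, (0, 100), e_sac_mv=-10.0)
        assert seg.aiding_fraction == pytest.approx(1.0)

    def test_falling_ramp_piecewise_geometry(self):
        # +20 -> -60 mV at constant rate: aiding only while V > -10,
        # i.e. 30 mV of the 80 mV drop -> exactly 0.375
        t = np.arange(0, 100.5, 0.5)
        trace = Trace(t, np.linspace(20, -60, len(t)))
        seg = phase_alignment(trace, (0, 100), e_sac_mv=-10.0)
        assert seg.aiding_fraction == pytest.approx(0.375, abs=1e-12)

    def test_symmetric_triangle_half_aiding(self):
        up = np.linspace(-60, 40, 101)
        v = np.concatenate([up, up[::-1][1:]])
        t = np.arange(len(v)) * 0.5
        trace = Trace(t, v)
        seg = phase_alignment(trace, (t[0], t[-1]), e_sac_mv=-10.0)
        assert seg.aiding_fraction == pytest.approx(0.5, abs=1e-12)

    def test_fractions_partition_unity(self, ap_train):
        _, trace, _ = ap_train
        bounds = detect_cycles(trace)
        seg = phase_alignment(trace, (bounds[0], bounds[1]), e_sac_mv=-10.0)
        assert 0.0 <= seg.aiding_fraction <= 1.0
        total = sum(b - a for a, b, _ in seg.intervals)
        assert total == pytest.approx(bounds[1] - bounds[0], rel=0.02)

    def test_aiding_fraction_increases_with_plateau(self):
        """Longer plateau (rabbit-like AP) spends more of the cycle moving
        toward the stretch-current reversal potential."""
        fractions = []
        for pl in (0.05, 0.10, 0.20, 0.30, 0.40):
            params = APShapeParams(plateau_fraction=pl, n_cycles=4, dt=0.1)
            trace, _ = gen_ap_train(params)
            bounds = detect_cycles(trace)
            seg = phase_alignment(trace, (bounds[0], bounds[1]), e_sac_mv=-10.0)
            fractions.append(seg.aiding_fraction)
        assert all(a < b for a, b in zip(fractions[:-1], fractions[1:]))


class TestGeneratorContracts:
    def test_seed_determinism(self):
        p = APShapeParams(seed=3)
        a, _ = gen_ap_train(p)
        b, _ = gen_ap_train(p)
        np.testing.assert_array_equal(a.values, b.values)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            APShapeParams(dd_fraction=0.7, plateau_fraction=0.4)

    def test_dt_larger_than_upstroke_rejected(self):
        with pytest.raises(ValueError):
            APShapeParams(upstroke_ms=1.0, dt=2.0)

    def test_features_per_cycle_covers_all_cycles(self, ap_train):
        params, trace, _ = ap_train
        rows = features_per_cycle(trace)
        assert len(rows) == params.n_cycles - 1
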