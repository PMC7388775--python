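"""Fiber direction, tortuosity, and crimp morphometrics."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sanstretch.fibers import (
    FiberPath,
    crimp_wavelength,
    fiber_direction,
    orientation_histogram,
    read_fiber_csv,
    read_swc,
    tortuosity,
    write_fiber_csv,
    write_swc,
)
from sanstretch.synthetic import FiberGenParams, gen_fiber


def straight_fiber(direction_deg, n=50, length=60.0):
    th = np.radians(direction_deg)
    s = np.linspace(0, length, n)
    return FiberPath(np.column_stack([s * np.cos(th), s * np.sin(th), np.zeros(n)]))


class TestFiberDirection:
    @pytest.mark.parametrize("angle", [0.0, 45.0, 90.0, 135.0, 179.0])
    def test_straight_fiber_angles(self, angle):
        assert fiber_direction(straight_fiber(angle)) == pytest.approx(angle, abs=1e-6)

    def test_folding_to_half_circle(self):
        # a fiber pointing at 225 deg is the same axial direction as 45 deg
        th = np.radians(225.0)
        s = np.linspace(0, 60, 50)
        path = FiberPath(np.column_stack([s * np.cos(th), s * np.sin(th), np.zeros(50)]))
        assert fiber_direction(path) == pytest.approx(45.0, abs=1e-6)

    def test_crimped_fiber_recovers_generating_direction(self):
        path, truth = gen_fiber(FiberGenParams(direction_deg=45.0, jitter_sd=0.2, seed=2))
        assert fiber_direction(path) == pytest.approx(45.0, abs=2.0)

    def test_degenerate_cloud_rejected(self):
        with pytest.raises(ValueError, match="distinct|dominant"):
            fiber_direction(FiberPath([[0, 0, 0], [0, 0, 0], [0, 0, 0]]))


class TestTortuosity:
    def test_straight_line_is_one(self):
        assert tortuosity(straight_fiber(30.0)) == pytest.approx(1.0, abs=1e-12)

    def test_sinusoid_quadrature_oracle(self):
        lam = 10.0
        params = FiberGenParams(
            crimp_wavelength=lam, crimp_amplitude=lam / (2 * np.pi),
            length=6 * lam, point_spacing=0.01,
        )
        path, truth = gen_fiber(params)
        assert truth["tortuosity"] == pytest.approx(1.2160, abs=2e-4)
        assert tortuosity(path) == pytest.approx(truth["tortuosity"], rel=1e-4)

    def test_semicircle(self):
        th = np.linspace(0, np.pi, 2001)
        path = FiberPath(np.column_stack([np.cos(th), np.sin(th), np.zeros_like(th)]))
        assert tortuosity(path) == pytest.approx(np.pi / 2, rel=1e-5)

    @given(
        angle=st.floats(0, 179, allow_nan=False),
        scale=st.floats(0.1, 10, allow_nan=False),
        shift=st.floats(-100, 100, allow_nan=False),
    )
    @settings(max_examples=30, deadline=None)
    def test_invariant_under_similarity_transforms(self, angle, scale, shift):
        path, _ = gen_fiber(FiberGenParams(seed=5))
        base = tortuosity(path)
        th = np.radians(angle)
        rot = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        moved = FiberPath(scale * path.points @ rot.T + shift)
        assert tortuosity(moved) == pytest.approx(base, rel=1e-9)
        assert tortuosity(moved) >= 1.0

    def test_increases_with_crimp_amplitude(self):
        torts = [
            gen_fiber(FiberGenParams(crimp_amplitude=a, point_spacing=0.05))[1]["tortuosity"]
            for a in (0.5, 1.0, 2.0, 4.0)
        ]
        assert all(a < b for a, b in zip(torts[:-1], torts[1:]))


class TestCrimpWavelength:
    def test_generator_wavelength_recovered(self):
        path, truth = gen_fiber(
            FiberGenParams(crimp_wavelength=10.0, crimp_amplitude=1.0, length=60.0)
        )
        wl = crimp_wavelength(path)
        assert len(wl) >= 3
        assert np.mean(wl) == pytest.approx(10.0, abs=0.2)

    def test_straight_fiber_yields_no_wavelengths(self):
        with pytest.warns(UserWarning):
            assert crimp_wavelength(straight_fiber(10.0)) == []

    def test_bow_without_crimp_detrended_away(self):
        path, _ = gen_fiber(
            FiberGenParams(crimp_amplitude=0.0, bow_amplitude=5.0, length=60.0)
        )
        with pytest.warns(UserWarning):
            assert crimp_wavelength(path) == []

    def test_crimp_survives_superimposed_bow(self):
        path, _ = gen_fiber(
            FiberGenParams(
                crimp_wavelength=10.0, crimp_amplitude=1.0, bow_amplitude=4.0, length=60.0
            )
        )
        wl = crimp_wavelength(path)
        assert len(wl) >= 3
        assert np.mean(wl) == pytest.approx(10.0, abs=0.6)


class TestOrientationHistogram:
    def test_single_direction_single_bin(self):
        h = orientation_histogram({"s1": [0.1] * 20})
        assert h.sample_fractions["s1"][0] == pytest.approx(1.0)
        assert h.alignment_fraction == pytest.approx(1.0)

    def test_fractions_sum_to_one_per_sample(self, rng):
        dirs = {f"s{i}": rng.uniform(0, 180, 50) for i in range(3)}
        h = orientation_histogram(dirs)
        for frac in h.sample_fractions.values():
            assert np.sum(frac) == pytest.approx(1.0)
        assert np.sum(h.mean_fractions) == pytest.approx(1.0)

    def test_uniform_directions_flatten_histogram(self, rng):
        h = orientation_histogram({"s": rng.uniform(0, 180, 10_000)})
        n_bins = len(h.mean_fractions)
        assert np.max(h.mean_fractions) == pytest.approx(1 / n_bins, rel=0.15)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            orientation_histogram({})


class TestFiberIO:
    def test_swc_round_trip(self, tmp_path):
        fibers = [gen_fiber(FiberGenParams(seed=s, jitter_sd=0.1))[0] for s in range(3)]
        path = tmp_path / "fibers.swc"
        write_swc(fibers, path)
        back = read_swc(path)
        assert len(back) == 3
        for a, b in zip(fibers, back):
            np.testing.assert_allclose(a.points, b.points, rtol=1e-5)

    def test_csv_round_trip(self, tmp_path):
        fibers = [gen_fiber(FiberGenParams(seed=s))[0] for s in range(2)]
        for i, f in enumerate(fibers):
            f.fiber_id = i
        path = tmp_path / "fibers.csv"
        write_fiber_csv(fibers, path)
        back = read_fiber_csv(path)
        assert len(back) == 2
        np.testing.assert_allclose(back[1].points, fibers[1].points, rtol=1e-12)


class TestFiberGenerator:
    def test_straight_fiber_truth(self):
        _, truth = gen_fiber(
            FiberGenParams(crimp_amplitude=0.0, bow_amplitude=0.0, jitter_sd=0.0)
        )
        assert truth["tortuosity"] == pytest.approx(1.0, abs=1e-9)

    def test_seed_determinism(self):
        p = FiberGenParams(jitter_sd=0.3, seed=8)
        a, _ = gen_fiber(p)
        b, _ = gen_fiber(p)
        np.testing.assert_array_equal(a.points, b.points)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            FiberGenParams(length=0.0)

    def test_truth_tortuosity_at_least_one(self):
        for seed in range(5):
            _, truth = gen_fiber(FiberGenParams(crimp_amplitude=1.5, bow_amplitude=2.0, seed=seed))
            assert truth["tortuosity"] >= 1.0
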