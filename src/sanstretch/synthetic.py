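"""Synthetic-data generators with analytic ground truth.

Every input the pipeline consumes can be generated here with known truth,
so each analysis stage is testable without any experimental recording:

* ``gen_ap_train`` — spontaneously oscillating SAN-like membrane-potential
  waveforms with controllable diastolic-depolarisation, plateau, and
  repolarisation phases (C1-smooth cosine-ramp segments);
* ``gen_beat_trace`` — ECG/force-like beat trains (positive spikes) with a
  controllable stretch-induced rate step, noise, and drift;
* ``gen_stress_strain`` — exponential stress-strain points with
  multiplicative noise;
* ``gen_fiber`` — 3-D crimped, bowed, oriented collagen-fiber polylines;
* ``gen_membrane`` — undulating membrane profiles decorated with caveolae.

All randomness flows from one explicit seed per call (no global state);
noise-free outputs are exactly invertible by the corresponding analysis
operation up to discretisation. Ground truth for curved geometry is always
computed on the jitter-free analytic curve by dense numerical quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fibers import FiberPath
from .membrane import MembraneProfile
from .trace import Trace

__all__ = [
    "APShapeParams",
    "BeatTrainParams",
    "FiberGenParams",
    "MembraneGenParams",
    "gen_ap_train",
    "gen_beat_trace",
    "gen_stress_strain",
    "gen_fiber",
    "gen_membrane",
]

# Fraction of the MDP->peak range at which the diastolic ramp hands over to
# the upstroke (takeoff potential).
TAKEOFF_FRAC = 0.15


# ---------------------------------------------------------------------------
# AP waveform trains


@dataclass(frozen=True)
class APShapeParams:
    """Shape parameters of the synthetic pacemaker AP waveform family.

    One cycle is four C1-joined cosine ramps: diastolic depolarisation
    (``dd_fraction`` of the cycle, MDP to takeoff), upstroke
    (``upstroke_ms``, takeoff to peak), plateau shoulder
    (``plateau_fraction`` of the cycle, peak down to the 20%-repolarisation
    level) and final repolarisation (the remainder, back to MDP).
    """

    mdp: float = -60.0  # mV
    peak: float = 20.0  # mV
    cycle_length: float = 150.0  # ms
    dd_fraction: float = 0.45
    plateau_fraction: float = 0.10
    upstroke_ms: float = 2.0
    n_cycles: int = 10
    dt: float = 0.1  # ms
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mdp >= self.peak:
            raise ValueError("mdp must be below peak")
        if not (0 < self.dd_fraction < 1) or not (0 <= self.plateau_fraction < 1):
            raise ValueError("fractions out of range")
        if self.dd_fraction + self.plateau_fraction >= 1:
            raise ValueError("dd_fraction + plateau_fraction must be < 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.dt > self.upstroke_ms:
            raise ValueError("dt must not exceed the upstroke duration")
        if (
            self.dd_fraction * self.cycle_length
            + self.upstroke_ms
            + self.plateau_fraction * self.cycle_length
            >= self.cycle_length
        ):
            raise ValueError("phases exceed the cycle length")


def _cos_ramp(v0: float, v1: float, tau: np.ndarray, T: float) -> np.ndarray:
    """C1 ramp v0 -> v1 over [0, T] with zero slope at both ends."""
    return v0 + (v1 - v0) * 0.5 * (1.0 - np.cos(np.pi * tau / T))


def _ap_waveform(params: APShapeParams, phase: np.ndarray) -> np.ndarray:
    """Analytic one-cycle waveform evaluated at phase in [0, CL)."""
    cl = params.cycle_length
    t_dd = params.dd_fraction * cl
    t_up = params.upstroke_ms
    t_pl = params.plateau_fraction * cl
    amp = params.peak - params.mdp
    v_take = params.mdp + TAKEOFF_FRAC * amp
    v20 = params.peak - 0.20 * amp

    v = np.empty_like(phase)
    seg = phase < t_dd
    v[seg] = _cos_ramp(params.mdp, v_take, phase[seg], t_dd)
    seg = (phase >= t_dd) & (phase < t_dd + t_up)
    v[seg] = _cos_ramp(v_take, params.peak, phase[seg] - t_dd, t_up)
    seg = (phase >= t_dd + t_up) & (phase < t_dd + t_up + t_pl)
    v[seg] = _cos_ramp(params.peak, v20, phase[seg] - t_dd - t_up, t_pl)
    seg = phase >= t_dd + t_up + t_pl
    t_rep = cl - t_dd - t_up - t_pl
    v[seg] = _cos_ramp(v20, params.mdp, phase[seg] - t_dd - t_up - t_pl, t_rep)
    return v


def gen_ap_train(params: APShapeParams) -> tuple[Trace, pd.DataFrame]:
    """Periodic AP train plus a per-cycle ground-truth feature table.

    The trace starts half a diastolic interval before the first MDP, so all
    ``n_cycles`` MDP minima are interior samples. The returned table has one
    row per cycle with the analytic MDP time, upstroke (max-dV/dt) time,
    APD20, diastolic-depolarisation slope, and beating rate.
    """
    cl = params.cycle_length
    t_dd = params.dd_fraction * cl
    t_up = params.upstroke_ms
    t_pl = params.plateau_fraction * cl
    t0 = t_dd / 2.0  # time of the first MDP

    n_samp = int(round(params.n_cycles * cl / params.dt)) + 1
    t = np.arange(n_samp) * params.dt
    phase = np.mod(t - t0, cl)
    v = _ap_waveform(params, phase)
    trace = Trace(t, v, units="mV")

    # analytic DD slope over the 10-60% diastolic window (dense evaluation
    # of the cosine ramp, independent of the trace sampling)
    tau = np.linspace(0.10 * t_dd, 0.60 * t_dd, 2001)
    amp = params.peak - params.mdp
    v_dd = _cos_ramp(params.mdp, params.mdp + TAKEOFF_FRAC * amp, tau, t_dd)
    dd_slope_mv_per_s = float(np.polyfit(tau, v_dd, 1)[0] * 1000.0)

    rows = []
    for k in range(params.n_cycles):
        mdp_time = t0 + k * cl
        rows.append(
            {
                "cycle": k,
                "mdp_time_ms": mdp_time,
                "upstroke_time_ms": mdp_time + t_dd + t_up / 2.0,
                "apd20_ms": t_up / 2.0 + t_pl,
                "dd_rate_mv_per_s": dd_slope_mv_per_s,
                "cycle_length_ms": cl,
                "br_bpm": 60000.0 / cl,
                "mdp_mv": params.mdp,
                "peak_mv": params.peak,
            }
        )
    return trace, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Beat trains


@dataclass(frozen=True)
class BeatTrainParams:
    """ECG/force-like beat-train parameters.

    ``step_bpm`` is a signed rate step applied while ``window`` (seconds) is
    active, emulating a stretch-induced chronotropic response. The spike
    morphology is a narrow Gaussian bump (peak times are all the analysis
    uses); ``fs_hz`` sets the uniform sampling rate.
    """

    baseline_bpm: float = 400.0
    step_bpm: float = 0.0
    window: tuple = (10.0, 40.0)  # seconds
    noise_sd: float = 0.0
    drift: float = 0.0  # units per second
    fs_hz: float = 1000.0
    spike_width_ms: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_bpm <= 0:
            raise ValueError("baseline_bpm must be positive")
        if self.window[0] >= self.window[1]:
            raise ValueError("window start must precede end")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.baseline_bpm + self.step_bpm <= 0:
            raise ValueError("stepped rate must remain positive")


def gen_beat_trace(
    params: BeatTrainParams, duration_s: float
) -> tuple[Trace, np.ndarray]:
    """Spike-train trace plus the true beat times (seconds).

    Beat times are laid down by stepping each inter-beat interval from the
    instantaneous rate (baseline, plus ``step_bpm`` inside the window);
    the trace is unit-amplitude Gaussian bumps at those times plus white
    noise and a linear drift.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(params.seed)

    beat_times = []
    t = 60.0 / params.baseline_bpm / 2.0  # first beat half an interval in
    while t < duration_s:
        beat_times.append(t)
        rate = params.baseline_bpm
        if params.window[0] <= t < params.window[1]:
            rate += params.step_bpm
        t += 60.0 / rate
    beat_times = np.array(beat_times)

    dt_ms = 1000.0 / params.fs_hz
    n = int(round(duration_s * params.fs_hz)) + 1
    time_ms = np.arange(n) * dt_ms
    time_s = time_ms / 1000.0
    sig = np.zeros(n)
    sigma_s = params.spike_width_ms / 1000.0 / 2.355  # FWHM -> sd
    half = 4.0 * sigma_s
    for bt in beat_times:
        sel = slice(
            max(int((bt - half) * params.fs_hz), 0),
            min(int((bt + half) * params.fs_hz) + 1, n),
        )
        sig[sel] += np.exp(-0.5 * ((time_s[sel] - bt) / sigma_s) ** 2)
    sig += params.drift * time_s
    if params.noise_sd > 0:
        sig += rng.normal(0.0, params.noise_sd, n)
    return Trace(time_ms, sig, units="a.u."), beat_times


# ---------------------------------------------------------------------------
# Stress-strain curves


def gen_stress_strain(
    alpha: float,
    beta: float,
    strain_grid,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Exponential stress-strain points with multiplicative Gaussian noise.

    ``stress_i = alpha * exp(beta * strain_i) * (1 + eps_i)`` with
    ``eps ~ Normal(0, noise_sd)``. Returns a
    :class:`~sanstretch.mechanics.StressStrainCurve`; the generating
    ``(alpha, beta)`` is the ground truth.
    """
    from .mechanics import StressStrainCurve

    strain = np.asarray(list(strain_grid), dtype=float)
    if strain.size == 0:
        raise ValueError("empty strain grid")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if np.any(strain < 0):
        raise ValueError("strains must be >= 0")
    rng = np.random.default_rng(seed)
    stress = alpha * np.exp(beta * strain)
    if noise_sd > 0:
        stress = stress * (1.0 + rng.normal(0.0, noise_sd, strain.size))
    return StressStrainCurve(strain=strain, stress_kpa=stress)


# ---------------------------------------------------------------------------
# Collagen fibers


@dataclass(frozen=True)
class FiberGenParams:
    """Crimped / bowed / oriented 3-D fiber parameters (lengths in µm)."""

    direction_deg: float = 0.0  # in [0, 180)
    crimp_wavelength: float = 10.0
    crimp_amplitude: float = 1.0
    bow_amplitude: float = 0.0  # one half-period bow over the whole fiber
    length: float = 60.0
    point_spacing: float = 0.25
    jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.crimp_wavelength <= 0 or self.point_spacing <= 0:
            raise ValueError("wavelength and point spacing must be positive")
        if self.length <= 0:
            raise ValueError("zero-length fiber rejected")
        if self.length < 2 * self.crimp_wavelength:
            raise ValueError("length must cover >= 2 crimp wavelengths")


def _fiber_analytic(params: FiberGenParams, s: np.ndarray) -> np.ndarray:
    """Jitter-free fiber points at axial positions ``s``."""
    th = math.radians(params.direction_deg)
    u = np.array([math.cos(th), math.sin(th), 0.0])
    n1 = np.array([-math.sin(th), math.cos(th), 0.0])  # in-plane normal
    lateral = params.crimp_amplitude * np.sin(
        2.0 * np.pi * s / params.crimp_wavelength
    ) + params.bow_amplitude * np.sin(np.pi * s / params.length)
    return s[:, None] * u[None, :] + lateral[:, None] * n1[None, :]


def gen_fiber(params: FiberGenParams) -> tuple[FiberPath, dict]:
    """3-D fiber polyline plus analytic ground-truth metrics.

    The fiber runs along ``direction_deg`` in the x-y plane with in-plane
    sinusoidal crimp and an optional half-period bow; Gaussian jitter is
    added per point. True tortuosity is computed by dense numerical
    arc-length quadrature of the jitter-free analytic curve.
    """
    rng = np.random.default_rng(params.seed)
    s = np.arange(0.0, params.length + params.point_spacing / 2, params.point_spacing)
    pts = _fiber_analytic(params, s)
    if params.jitter_sd > 0:
        pts = pts + rng.normal(0.0, params.jitter_sd, pts.shape)

    # dense quadrature on the analytic curve for true tortuosity
    s_dense = np.linspace(0.0, params.length, 20001)
    dense = _fiber_analytic(params, s_dense)
    arc = float(np.sum(np.linalg.norm(np.diff(dense, axis=0), axis=1)))
    chord = float(np.linalg.norm(dense[-1] - dense[0]))
    truth = {
        "direction_deg": params.direction_deg % 180.0,
        "tortuosity": arc / chord,
        "crimp_wavelength_um": params.crimp_wavelength,
        "n_periods": params.length / params.crimp_wavelength,
    }
    return FiberPath(pts), truth


# ---------------------------------------------------------------------------
# Membrane profiles with caveolae


@dataclass(frozen=True)
class MembraneGenParams:
    """Undulating membrane profile decorated with caveolae.

    The contour is ``y(x) = A sin(2 pi x / lambda)`` over ``profile_length``
    (µm; coordinates in nm). Caveolae are flask markers placed at Poisson
    positions along the contour with the requested mean areal density
    (count per µm², using ``slice_thickness_nm`` to convert profile arc
    length to membrane area).
    """

    undulation_amplitude: float = 50.0  # nm
    undulation_wavelength: float = 500.0  # nm
    caveola_density_true: float = 2.0  # count per µm²
    caveola_radius: float = 30.0  # nm
    profile_length: float = 10.0  # µm
    slice_thickness_nm: float = 275.0
    point_spacing_nm: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for val in (
            self.undulation_wavelength,
            self.caveola_radius,
            self.profile_length,
            self.slice_thickness_nm,
            self.point_spacing_nm,
        ):
            if val <= 0:
                raise ValueError("lengths must be positive")
        if self.undulation_amplitude < 0 or self.caveola_density_true < 0:
            raise ValueError("amplitude and density must be >= 0")


def gen_membrane(
    params: MembraneGenParams, max_retries: int = 100
) -> tuple[MembraneProfile, dict]:
    """Membrane profile plus ground-truth caveolae statistics.

    Caveola count is Poisson with mean ``density * arc_length * thickness``;
    markers are placed uniformly along the contour, kept at least two radii
    apart (resampled up to ``max_retries``, then an error). The true
    convolution index comes from dense quadrature of the analytic sinusoid.
    """
    rng = np.random.default_rng(params.seed)
    length_nm = params.profile_length * 1000.0
    x = np.arange(0.0, length_nm + params.point_spacing_nm / 2, params.point_spacing_nm)
    lam = params.undulation_wavelength
    amp = params.undulation_amplitude
    y = amp * np.sin(2.0 * np.pi * x / lam)
    points = np.column_stack([x, y])

    # dense quadrature for the true arc length
    xd = np.linspace(0.0, length_nm, 200001)
    yd = amp * np.sin(2.0 * np.pi * xd / lam)
    arc_nm = float(np.sum(np.hypot(np.diff(xd), np.diff(yd))))
    convolution_true = (arc_nm / length_nm - 1.0) * 100.0

    area_um2 = arc_nm * params.slice_thickness_nm * 1e-6
    n_cav = int(rng.poisson(params.caveola_density_true * area_um2))

    min_sep = 2.0 * params.caveola_radius
    for _ in range(max_retries):
        xs = np.sort(rng.uniform(0.0, length_nm, n_cav))
        if n_cav < 2 or np.all(np.diff(xs) >= min_sep):
            break
    else:
        raise RuntimeError(
            f"could not place {n_cav} non-overlapping caveolae in "
            f"{max_retries} attempts"
        )
    # markers sit just beneath the membrane contour
    cav = np.column_stack(
        [xs, amp * np.sin(2.0 * np.pi * xs / lam) - params.caveola_radius]
    )
    profile = MembraneProfile(
        points=points, caveolae=cav, slice_thickness_nm=params.slice_thickness_nm
    )
    # 2-D flask model: each caveola contributes a circle circumference of
    # extra membrane relative to the smooth outline
    excess_pct = (
        100.0 * n_cav * 2.0 * np.pi * params.caveola_radius / arc_nm
        if arc_nm > 0
        else 0.0
    )
    truth = {
        "convolution_pct": convolution_true,
        "n_caveolae": n_cav,
        "expected_n_caveolae": params.caveola_density_true * area_um2,
        "density_per_um2": n_cav / area_um2,
        "density_true_per_um2": params.caveola_density_true,
        "membrane_area_um2": area_um2,
        "caveolar_excess_pct": excess_pct,
    }
    return profile, truth
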