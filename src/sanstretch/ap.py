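"""Action-potential morphometrics and stretch-current phase alignment.

Extracts pacemaker AP features (maximum diastolic potential, peak, cycle
length and beating rate, APD20, diastolic-depolarisation rate, upstroke
timing) from any voltage trace, and segments each cycle into phases where a
stretch-activated current with reversal potential ``e_sac`` would *aid*
(membrane potential moving toward ``e_sac``) or *oppose* (moving away) the
intrinsic voltage change. The balance of aiding vs opposing time over the
cycle predicts the sign of the chronotropic response to sustained stretch:
species with long diastolic depolarisation and plateau (rabbit-like AP)
spend most of the cycle in aiding phases, whereas the compressed mouse AP
is near-evenly balanced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .trace import Trace

__all__ = [
    "APFeatures",
    "PhaseSegmentation",
    "detect_cycles",
    "features",
    "features_per_cycle",
    "phase_alignment",
]


@dataclass
class APFeatures:
    """Morphology features of one pacemaker cycle."""

    mdp_mv: float
    peak_mv: float
    cycle_length_ms: float
    br_bpm: float
    apd20_ms: float
    dd_rate_mv_per_s: float
    upstroke_time_ms: float
    max_dvdt_mv_per_ms: float


@dataclass
class PhaseSegmentation:
    """Aiding/opposing partition of one cycle for a given reversal potential."""

    intervals: list  # (t_start_ms, t_end_ms, "aiding" | "opposing")
    aiding_fraction: float
    weighted_index_mv: float  # cycle-average of sign(dV/dt) * (e_sac - V)


def detect_cycles(trace: Trace, refractory_frac: float = 0.4) -> np.ndarray:
    """Cycle boundaries: times of local voltage minima (MDP times).

    Minima are found twice: once unconstrained to estimate the median
    inter-minimum interval, then with a refractory distance of
    ``refractory_frac`` times that interval to reject double detections.
    First and last samples are never boundaries, so partial edge cycles are
    implicitly discarded.
    """
    v = trace.values
    minima, _ = find_peaks(-v)
    if len(minima) < 2:
        raise ValueError("no oscillation: fewer than 2 voltage minima")
    med = np.median(np.diff(minima))
    distance = max(int(round(refractory_frac * med)), 1)
    # height filter keeps only minima near the global diastolic level
    depth = np.percentile(v, 95) - np.percentile(v, 5)
    minima, _ = find_peaks(-v, distance=distance, prominence=0.25 * depth)
    if len(minima) < 2:
        raise ValueError("no oscillation: fewer than 2 voltage minima")
    return trace.time_ms[minima]


def _cycle_slice(trace: Trace, cycle: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    t0, t1 = cycle
    sel = (trace.time_ms >= t0) & (trace.time_ms <= t1)
    if not np.any(sel):
        raise ValueError("cycle window outside trace")
    return trace.time_ms[sel], trace.values[sel]


def features(trace: Trace, cycle: tuple[float, float]) -> APFeatures:
    """Extract :class:`APFeatures` for one cycle (MDP-to-MDP window).

    Conventions: the upstroke time is the maximum of dV/dt; APD20 runs from
    the upstroke time until V first falls below
    ``peak - 0.20 * (peak - following MDP)``; the diastolic-depolarisation
    rate is the least-squares slope of V(t) over 10-60% of the interval from
    the initial MDP to upstroke onset, onset being the first time dV/dt
    exceeds 5% of its maximum.
    """
    t, v = _cycle_slice(trace, cycle)
    if len(t) < 5:
        raise ValueError("cycle too short")
    dt = t[1] - t[0]
    mdp_end = float(v[-1])  # following MDP bounds the cycle
    peak_idx = int(np.argmax(v))
    peak = float(v[peak_idx])
    mdp = float(np.min(v))
    cl = float(t[-1] - t[0])

    dvdt = np.gradient(v, t)
    up_idx = int(np.argmax(dvdt))
    upstroke_time = float(t[up_idx])
    max_dvdt = float(dvdt[up_idx])

    # APD20: first downward crossing of the 20%-repolarisation level after
    # the upstroke
    v20 = peak - 0.20 * (peak - mdp_end)
    after = np.arange(peak_idx, len(v))
    below = after[v[after] < v20]
    if below.size == 0:
        raise ValueError("cycle has no 20%-repolarisation crossing")
    cross = below[0]
    # linear interpolation between the bracketing samples
    if cross > 0 and v[cross - 1] != v[cross]:
        frac = (v[cross - 1] - v20) / (v[cross - 1] - v[cross])
        t_cross = t[cross - 1] + frac * dt
    else:
        t_cross = t[cross]
    apd20 = float(t_cross - upstroke_time)

    # DD slope over 10-60% of MDP -> upstroke-onset interval
    mdp_idx = int(np.argmin(v[: up_idx + 1]))
    onset_candidates = np.flatnonzero(dvdt[mdp_idx : up_idx + 1] > 0.05 * max_dvdt)
    onset_idx = mdp_idx + (int(onset_candidates[0]) if onset_candidates.size else up_idx - mdp_idx)
    span = t[onset_idx] - t[mdp_idx]
    lo = t[mdp_idx] + 0.10 * span
    hi = t[mdp_idx] + 0.60 * span
    win = (t >= lo) & (t <= hi)
    if np.sum(win) < 2:
        raise ValueError("diastolic interval too short for a slope fit")
    slope_per_ms = np.polyfit(t[win], v[win], 1)[0]

    return APFeatures(
        mdp_mv=mdp,
        peak_mv=peak,
        cycle_length_ms=cl,
        br_bpm=60000.0 / cl,
        apd20_ms=apd20,
        dd_rate_mv_per_s=float(slope_per_ms * 1000.0),
        upstroke_time_ms=upstroke_time,
        max_dvdt_mv_per_ms=max_dvdt,
    )


def features_per_cycle(trace: Trace) -> list[APFeatures]:
    """Features for every complete MDP-to-MDP cycle in the trace."""
    bounds = detect_cycles(trace)
    return [features(trace, (a, b)) for a, b in zip(bounds[:-1], bounds[1:])]


def phase_alignment(
    trace: Trace, cycle: tuple[float, float], e_sac_mv: float = -10.0
) -> PhaseSegmentation:
    """Partition one cycle into aiding vs opposing phases for ``e_sac``.

    A sample is *aiding* where ``sign(dV/dt) * sign(e_sac - V) > 0`` (the
    membrane potential is moving toward the reversal potential, so the
    stretch current accelerates the intrinsic change) and *opposing* where
    the product is negative. Zero-measure boundary samples (dV/dt = 0 or
    V = e_sac) join the preceding interval. ``aiding_fraction`` and the
    driving-force-weighted index are trapezoidal time averages.
    """
    t, v = _cycle_slice(trace, cycle)
    if len(t) < 3:
        raise ValueError("cycle too short")

    # The trace is piecewise linear between samples, so within one step the
    # slope sign is fixed and the aiding condition
    # sign(dV/dt) * sign(e_sac - V) > 0 can only switch where V crosses
    # e_sac; that crossing is located exactly by interpolation. Zero-slope
    # steps are zero-measure decisions assigned to the preceding label.
    aiding_time = 0.0
    prev_label = 0
    for i in range(len(t) - 1):
        a, b = v[i], v[i + 1]
        dt_step = t[i + 1] - t[i]
        dv = b - a
        if dv == 0.0:
            seg = [(dt_step, prev_label if prev_label != 0 else 1)]
        else:
            s = 1.0 if dv > 0 else -1.0

            def lab(x: float) -> int:
                prod = s * (e_sac_mv - x)
                if prod > 0:
                    return 1
                if prod < 0:
                    return -1
                return prev_label if prev_label != 0 else 1

            la, lb = lab(a), lab(b)
            if la == lb:
                seg = [(dt_step, la)]
            else:
                tau = (e_sac_mv - a) / dv * dt_step
                tau = min(max(tau, 0.0), dt_step)
                seg = [(tau, la), (dt_step - tau, lb)]
        for dur, label in seg:
            if dur <= 0:
                continue
            if label > 0:
                aiding_time += dur
            prev_label = label

    # intervals at sample resolution (boundary samples join the preceding run)
    dvdt = np.gradient(v, t)
    sgn = np.sign(dvdt) * np.sign(e_sac_mv - v)
    labels = np.zeros(len(t), dtype=int)
    labels[0] = 1 if sgn[0] >= 0 else -1
    for i in range(1, len(t)):
        labels[i] = labels[i - 1] if sgn[i] == 0 else (1 if sgn[i] > 0 else -1)
    intervals = []
    run_start = 0
    for i in range(1, len(t) + 1):
        if i == len(t) or labels[i] != labels[run_start]:
            intervals.append(
                (
                    float(t[run_start]),
                    float(t[min(i, len(t) - 1)]),
                    "aiding" if labels[run_start] > 0 else "opposing",
                )
            )
            run_start = i

    total = float(t[-1] - t[0])
    weighted = float(np.trapezoid(np.sign(dvdt) * (e_sac_mv - v), t) / total)
    return PhaseSegmentation(
        intervals=intervals,
        aiding_fraction=aiding_time / total,
        weighted_index_mv=weighted,
    )
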