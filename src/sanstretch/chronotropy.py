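"""Beating-rate responses to stretch and their relation to tissue stiffness.

Takes ECG or force traces plus a stretch protocol and produces, per
preparation: beat times (peak detection), an instantaneous beating-rate
series, the per-strain stretch response (signed % change in BR during the
stretch window relative to the preceding baseline, repeats averaged), the
largest absolute response, and the across-preparation ordinary
least-squares regression of that response against the exponential stiffness
index beta.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.signal import find_peaks, medfilt

from .trace import Trace

__all__ = [
    "StretchStep",
    "ResponseRecord",
    "RegressionResult",
    "find_beats",
    "br_series",
    "stretch_response",
    "average_repeats",
    "largest_abs_response",
    "response_vs_stiffness",
]

#: QC threshold used for mouse preparations: exclude low baseline BR.
LOW_BASELINE_BPM = 290.0


@dataclass(frozen=True)
class StretchStep:
    """One application of a given strain: baseline window then stretch window."""

    strain: float
    stretch_window: tuple  # (t_start_s, t_end_s), nominally 30 s long
    baseline_window: tuple  # (t_start_s, t_end_s)
    repeat_index: int = 1

    def __post_init__(self) -> None:
        b0, b1 = self.baseline_window
        s0, s1 = self.stretch_window
        if b0 >= b1 or s0 >= s1:
            raise ValueError("window start must precede end")
        if b1 > s0:
            raise ValueError("baseline window must precede the stretch window")


@dataclass
class ResponseRecord:
    """Stretch response at one strain (possibly averaged over repeats)."""

    strain: float
    delta_br_pct: float
    br_baseline_bpm: float
    averaged_over_repeats: bool = False
    low_baseline_flag: bool = False


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p: float
    n: int


def find_beats(
    trace: Trace,
    min_rate_bpm: float = 60.0,
    max_rate_bpm: float = 600.0,
    prominence_frac: float = 0.3,
) -> np.ndarray:
    """Beat times (seconds) from the peaks of an ECG or force signal.

    Peaks must exceed ``prominence_frac`` of the robust amplitude range
    (5th-95th percentile) and respect a refractory interval of
    ``60 / max_rate_bpm`` s, so doubled-peak morphologies within one
    refractory window are counted once.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    if max_rate_bpm <= min_rate_bpm:
        raise ValueError("max_rate_bpm must exceed min_rate_bpm")
    v = trace.values
    lo, hi = np.percentile(v, [5, 95])
    rng = hi - lo
    if rng <= 0:
        # sparse spikes on a flat baseline: percentiles collapse, fall back
        # to the full amplitude range
        rng = float(np.max(v) - np.min(v))
    if rng <= 0:
        return np.array([])
    distance = max(int(round(60.0 / max_rate_bpm * trace.fs_hz)), 1)
    peaks, _ = find_peaks(v, prominence=prominence_frac * rng, distance=distance)
    return trace.time_ms[peaks] / 1000.0


def br_series(beat_times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous beating rate: ``BR_i = 60 / (t_i - t_{i-1})`` at ``t_i``.

    Returns ``(times_s, br_bpm)``, one value per inter-beat interval.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size < 2:
        raise ValueError("need >= 2 beats for a rate series")
    intervals = np.diff(beat_times)
    if np.any(intervals <= 0):
        raise ValueError("beat times must be strictly increasing (no duplicates)")
    return beat_times[1:], 60.0 / intervals


def stretch_response(
    beat_times: np.ndarray,
    step: StretchStep,
    min_beats: int = 5,
    mode: str = "peak",
) -> ResponseRecord:
    """Signed percent BR change during one stretch application.

    Baseline BR is the mean instantaneous rate in the baseline window. The
    response is, in ``mode="peak"`` (default), the signed value of the
    largest-magnitude deviation of the 3-beat median-smoothed BR series
    within the stretch window, as a percent of baseline; ``mode="mean"``
    uses the window-mean deviation instead.
    """
    t, br = br_series(beat_times)
    base_sel = (t >= step.baseline_window[0]) & (t < step.baseline_window[1])
    str_sel = (t >= step.stretch_window[0]) & (t < step.stretch_window[1])
    if np.sum(base_sel) < min_beats:
        raise ValueError(
            f"only {int(np.sum(base_sel))} beats in the baseline window "
            f"(need {min_beats})"
        )
    if np.sum(str_sel) < min_beats:
        raise ValueError(
            f"only {int(np.sum(str_sel))} beats in the stretch window "
            f"(need {min_beats})"
        )
    br_base = float(np.mean(br[base_sel]))
    smooth = medfilt(br[str_sel], kernel_size=3)
    dev = smooth - br_base
    if mode == "peak":
        delta = float(dev[np.argmax(np.abs(dev))])
    elif mode == "mean":
        delta = float(np.mean(dev))
    else:
        raise ValueError("mode must be 'peak' or 'mean'")
    return ResponseRecord(
        strain=step.strain,
        delta_br_pct=100.0 * delta / br_base,
        br_baseline_bpm=br_base,
        low_baseline_flag=br_base < LOW_BASELINE_BPM,
    )


def average_repeats(records) -> list[ResponseRecord]:
    """Average the two repeated stretches at each strain into one record."""
    by_strain: dict[float, list[ResponseRecord]] = {}
    for rec in records:
        by_strain.setdefault(rec.strain, []).append(rec)
    out = []
    for strain in sorted(by_strain):
        group = by_strain[strain]
        if len(group) != 2:
            warnings.warn(
                f"strain {strain}: {len(group)} repeat(s), expected 2", stacklevel=2
            )
        out.append(
            ResponseRecord(
                strain=strain,
                delta_br_pct=float(np.mean([g.delta_br_pct for g in group])),
                br_baseline_bpm=float(np.mean([g.br_baseline_bpm for g in group])),
                averaged_over_repeats=len(group) == 2,
                low_baseline_flag=any(g.low_baseline_flag for g in group),
            )
        )
    return out


def largest_abs_response(records) -> tuple[float, float]:
    """Largest absolute percent BR change across strains for one preparation.

    Returns ``(|delta_br|_max, strain_at_max)``; ties break toward the
    lower strain.
    """
    records = list(records)
    if not records:
        raise ValueError("no response records")
    best = None
    for rec in sorted(records, key=lambda r: r.strain):
        mag = abs(rec.delta_br_pct)
        if best is None or mag > best[0]:
            best = (mag, rec.strain)
    return best


def response_vs_stiffness(pairs) -> RegressionResult:
    """OLS regression of largest absolute BR response on stiffness beta.

    ``pairs`` is an iterable of ``(beta, largest_abs_response_pct)``.
    Returns slope, intercept, Pearson r, and the two-sided p-value for a
    non-zero slope.
    """
    pairs = np.asarray(list(pairs), dtype=float)
    if pairs.ndim != 2 or pairs.shape[0] < 3:
        raise ValueError("need >= 3 (beta, response) pairs")
    x, y = pairs[:, 0], pairs[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("degenerate regression: no variance in beta")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p=float(res.pvalue),
        n=int(pairs.shape[0]),
    )
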