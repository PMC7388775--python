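"""Pacemaker-cell electrophysiology with a stretch-activated current.

The simulator is built around a plug-in :class:`CellModel` contract: a model
names its gating states and membrane currents (pA/pF, capacitance
normalised), and the forward-Euler integrator advances

    dV_m/dt = -sum(scaled currents)        [pA/pF == mV/ms]

with a fixed time step (default 0.1 ms, runs to a 10 s quasi-steady state).
Stretch is modelled as an instantly activating, non-inactivating,
cation-non-selective stretch-activated current with a linear
current-voltage relationship,

    I_SAC,NS = g_SAC,NS * (V_m - E_SAC,NS),

with E_SAC,NS = -10 mV and a whole-cell conductance (per unit capacitance)
of 0.000248 nS/pF by default; ``calibrate_g_sac`` recovers the conductance
that depolarises the maximum diastolic potential by a chosen fraction.
Pharmacological block of rapidly activating potassium currents (4-AP) is a
multiplicative conductance scaling: transient outward current to zero,
delayed rectifier to 75%.

A published mouse SAN action-potential model can be supplied externally via
``load_cell_model("package.module:factory")``; everything in this repository
runs on the tunable :class:`DemoPacemakerModel`.
"""

from __future__ import annotations

import copy
import importlib
import json
import math
from abc import ABC, abstractmethod
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SACParams",
    "CellModel",
    "DemoPacemakerModel",
    "SimulationResult",
    "FOUR_AP",
    "i_sac_ns",
    "apply_pharmacology",
    "integrate",
    "calibrate_g_sac",
    "load_cell_model",
    "BracketingError",
]

#: 4-AP preset: transient outward K current abolished, delayed rectifier
#: reduced by 25%.
FOUR_AP = {"I_to": 0.0, "I_K_delayed": 0.75}


@dataclass(frozen=True)
class SACParams:
    """Stretch-activated non-selective cation current parameters.

    ``g_sac`` is the maximum whole-cell conductance per unit capacitance
    (nS/pF); ``e_sac`` the reversal potential (mV).
    """

    g_sac: float = 0.000248
    e_sac: float = -10.0

    def __post_init__(self) -> None:
        if self.g_sac < 0:
            raise ValueError("g_sac must be >= 0")


def i_sac_ns(v_m: float, p: SACParams) -> float:
    """Linear, instantly activating stretch-activated current (pA/pF).

    Inward (negative, depolarising) for ``v_m < e_sac``, outward above, zero
    at the reversal potential.
    """
    return p.g_sac * (v_m - p.e_sac)


class CellModel(ABC):
    """Plug-in contract for a capacitance-normalised pacemaker cell model.

    Implementations define gating-state dynamics and named membrane
    currents in pA/pF; the integrator owns the membrane-potential update
    ``dV/dt = -sum(scaled currents)``. ``current_scales`` holds per-current
    multiplicative modifiers (pharmacology), defaulting to 1.
    """

    name: str = "cell"
    state_names: list
    current_names: list
    v_init: float

    def __init__(self) -> None:
        self.current_scales = {nm: 1.0 for nm in self.current_names}

    @abstractmethod
    def initial_state(self) -> np.ndarray:
        """Initial gating-state vector (aligned with ``state_names``)."""

    @abstractmethod
    def currents(self, state: np.ndarray, v_m: float) -> np.ndarray:
        """Unscaled currents in pA/pF, aligned with ``current_names``."""

    @abstractmethod
    def state_derivatives(
        self, state: np.ndarray, v_m: float, i_total: float
    ) -> np.ndarray:
        """Gating-state rates (1/ms), aligned with ``state_names``."""

    def scale_vector(self) -> np.ndarray:
        return np.array([self.current_scales[nm] for nm in self.current_names])


def apply_pharmacology(model: CellModel, scales: dict) -> CellModel:
    """Return a copy of ``model`` with currents multiplicatively scaled.

    Scaling composes: applying ``a`` then ``b`` equals applying ``a*b`` per
    current. Unknown current names and negative scales are rejected.
    """
    for name, s in scales.items():
        if name not in model.current_names:
            raise KeyError(f"unknown current {name!r}; model has {model.current_names}")
        if s < 0:
            raise ValueError(f"negative scale {s} for current {name!r}")
    scaled = copy.deepcopy(model)
    for name, s in scales.items():
        scaled.current_scales[name] = scaled.current_scales.get(name, 1.0) * s
    return scaled


def _sigmoid(v: float, vh: float, k: float) -> float:
    return 1.0 / (1.0 + math.exp(-(v - vh) / k))


class DemoPacemakerModel(CellModel):
    """Minimal five-current Hodgkin-Huxley-style pacemaker cell.

    Not a transcription of any published model: a compact cell built for
    this pipeline, tuned to a mouse-like SAN phenotype (cycle length
    130-170 ms, MDP around -60 mV, brief AP) so that pharmacology and
    stretch interventions can be exercised without external model files.

    Currents (pA/pF): L-type calcium (``I_Ca_L``, upstroke), delayed
    rectifier potassium (``I_K_delayed``, repolarisation; deactivates
    quickly at diastolic potentials so its block barely touches diastole),
    transient outward potassium (``I_to``, early repolarisation), funny
    current (``I_f``, hyperpolarisation-activated inward) and a background
    sodium leak (``I_b_Na``) which together drive diastolic depolarisation.
    """

    name = "demo"
    state_names = ["d", "f", "n", "r", "q", "y"]
    current_names = ["I_Ca_L", "I_K_delayed", "I_to", "I_f", "I_b_Na"]
    v_init = -60.0

    def __init__(
        self,
        g_ca_l: float = 0.55,
        g_k: float = 0.4,
        g_to: float = 0.18,
        g_f: float = 0.018,
        g_b_na: float = 0.0008,
        e_ca: float = 60.0,
        e_k: float = -85.0,
        e_f: float = -20.0,
        e_b_na: float = 30.0,
        d_vh: float = -28.0,
        d_k: float = 4.0,
        tau_f_ms: float = 20.0,
        tau_y_ms: float = 40.0,
    ) -> None:
        self.g_ca_l = g_ca_l
        self.g_k = g_k
        self.g_to = g_to
        self.g_f = g_f
        self.g_b_na = g_b_na
        self.e_ca = e_ca
        self.e_k = e_k
        self.e_f = e_f
        self.e_b_na = e_b_na
        self.d_vh = d_vh
        self.d_k = d_k
        self.tau_f_ms = tau_f_ms
        self.tau_y_ms = tau_y_ms
        super().__init__()

    def initial_state(self) -> np.ndarray:
        v = self.v_init
        return np.array(
            [
                _sigmoid(v, self.d_vh, self.d_k),  # d
                _sigmoid(v, -40.0, -5.0),          # f
                _sigmoid(v, -20.0, 5.0),           # n
                _sigmoid(v, -20.0, 6.0),           # r
                _sigmoid(v, -50.0, -5.0),          # q
                _sigmoid(v, -70.0, -6.0),          # y
            ]
        )

    def currents(self, state: np.ndarray, v_m: float) -> np.ndarray:
        d, f, n, r, q, y = state
        return np.array(
            [
                self.g_ca_l * d * f * (v_m - self.e_ca),
                self.g_k * n * (v_m - self.e_k),
                self.g_to * r * q * (v_m - self.e_k),
                self.g_f * y * (v_m - self.e_f),
                self.g_b_na * (v_m - self.e_b_na),
            ]
        )

    def state_derivatives(
        self, state: np.ndarray, v_m: float, i_total: float
    ) -> np.ndarray:
        d, f, n, r, q, y = state
        v = v_m
        tau_n = 4.0 + 16.0 * _sigmoid(v, -40.0, 6.0)  # fast deactivation in diastole
        return np.array(
            [
                (_sigmoid(v, self.d_vh, self.d_k) - d) / 1.0,
                (_sigmoid(v, -40.0, -5.0) - f) / self.tau_f_ms,
                (_sigmoid(v, -20.0, 5.0) - n) / tau_n,
                (_sigmoid(v, -20.0, 6.0) - r) / 1.5,
                (_sigmoid(v, -50.0, -5.0) - q) / 25.0,
                (_sigmoid(v, -70.0, -6.0) - y) / self.tau_y_ms,
            ]
        )


@dataclass
class SimulationResult:
    """Voltage and per-current traces from one integration run."""

    time_ms: np.ndarray
    v_m: np.ndarray
    currents: dict  # current name -> pA/pF trace (scaled, as integrated)
    dt_ms: float
    duration_ms: float
    sac: SACParams | None = None
    current_scales: dict = field(default_factory=dict)

    def voltage_trace(self):
        from .trace import Trace

        return Trace(self.time_ms, self.v_m, units="mV")

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"time_ms": self.time_ms, "v_m_mv": self.v_m})
        for name, tr in self.currents.items():
            df[name] = tr
        df.to_csv(path, index=False)

    def summary_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "dt_ms": self.dt_ms,
                    "duration_ms": self.duration_ms,
                    "sac": None
                    if self.sac is None
                    else {"g_sac": self.sac.g_sac, "e_sac": self.sac.e_sac},
                    "current_scales": self.current_scales,
                    "v_min_mv": float(np.min(self.v_m)),
                    "v_max_mv": float(np.max(self.v_m)),
                },
                fh,
                indent=2,
            )


def integrate(
    model: CellModel,
    duration_ms: float = 10000.0,
    dt_ms: float = 0.1,
    sac: SACParams | None = None,
) -> SimulationResult:
    """Forward-Euler integration of ``model``, recording every current.

    When ``sac`` is given, ``i_sac_ns`` is added to the summed current at
    every step and recorded as ``I_SAC_NS``. A non-finite state aborts with
    the offending step index.
    """
    if duration_ms <= 0 or dt_ms <= 0:
        raise ValueError("duration and dt must be positive")
    n_steps = int(round(duration_ms / dt_ms))
    n_cur = len(model.current_names)
    scales = model.scale_vector()

    time = np.arange(n_steps + 1) * dt_ms
    v_trace = np.empty(n_steps + 1)
    cur_traces = np.empty((n_cur, n_steps + 1))
    sac_trace = np.empty(n_steps + 1) if sac is not None else None

    v = float(model.v_init)
    state = model.initial_state().astype(float)
    for k in range(n_steps + 1):
        cur = model.currents(state, v) * scales
        i_tot = float(np.sum(cur))
        if sac is not None:
            i_s = i_sac_ns(v, sac)
            sac_trace[k] = i_s
            i_tot += i_s
        v_trace[k] = v
        cur_traces[:, k] = cur
        if k == n_steps:
            break
        dstate = model.state_derivatives(state, v, i_tot)
        v = v - dt_ms * i_tot
        state = state + dt_ms * dstate
        if not (math.isfinite(v) and np.all(np.isfinite(state))):
            raise FloatingPointError(
                f"non-finite state at step {k + 1} (t = {(k + 1) * dt_ms:.3f} ms)"
            )

    currents = {nm: cur_traces[i] for i, nm in enumerate(model.current_names)}
    if sac is not None:
        currents["I_SAC_NS"] = sac_trace
    return SimulationResult(
        time_ms=time,
        v_m=v_trace,
        currents=currents,
        dt_ms=dt_ms,
        duration_ms=n_steps * dt_ms,
        sac=sac,
        current_scales=dict(model.current_scales),
    )


def steady_state_mdp(
    result: SimulationResult, n_cycles: int = 10, cv_warn: float = 0.01
) -> float:
    """Mean MDP over the last ``n_cycles`` complete cycles.

    Warns if the cycle-length coefficient of variation over that window
    exceeds ``cv_warn`` (quasi-steady-state check).
    """
    import warnings

    from .ap import detect_cycles

    bounds = detect_cycles(result.voltage_trace())
    if len(bounds) < n_cycles + 1:
        raise ValueError(f"fewer than {n_cycles} complete cycles in the run")
    tail = bounds[-(n_cycles + 1):]
    cls = np.diff(tail)
    if np.std(cls) / np.mean(cls) > cv_warn:
        warnings.warn(
            f"cycle-length CV {np.std(cls) / np.mean(cls):.3%} exceeds "
            f"{cv_warn:.0%}: run may not be at steady state",
            stacklevel=2,
        )
    t, v = result.time_ms, result.v_m
    mdps = [
        float(np.min(v[(t >= a) & (t <= b)])) for a, b in zip(tail[:-1], tail[1:])
    ]
    return float(np.mean(mdps))


class BracketingError(RuntimeError):
    """SAC conductance search could not bracket the target MDP reduction
    (the current suppresses oscillation before the target is reached)."""


def calibrate_g_sac(
    model: CellModel,
    target_mdp_reduction: float = 0.10,
    e_sac: float = -10.0,
    tolerance: float = 0.005,
    duration_ms: float = 10000.0,
    dt_ms: float = 0.1,
    max_iter: int = 60,
) -> float:
    """Bisect the SAC conductance producing a target |MDP| reduction.

    Finds ``g`` such that the steady-state ``|MDP|`` with the stretch
    current equals ``(1 - target) * |MDP|`` without it, within
    ``tolerance`` (relative). The upper bracket is doubled from 1e-4 nS/pF
    until the reduction is exceeded; loss of oscillation during bracketing
    raises :class:`BracketingError`, distinct from plain non-convergence.
    """
    if not 0 <= target_mdp_reduction < 1:
        raise ValueError("target reduction must be in [0, 1)")
    if target_mdp_reduction == 0:
        return 0.0

    mdp0 = steady_state_mdp(integrate(model, duration_ms, dt_ms))

    def reduction(g: float) -> float:
        res = integrate(model, duration_ms, dt_ms, sac=SACParams(g, e_sac))
        try:
            mdp = steady_state_mdp(res)
        except ValueError as err:
            raise BracketingError(
                f"oscillation lost at g = {g:.6g} nS/pF before reaching the "
                f"target reduction"
            ) from err
        return 1.0 - abs(mdp) / abs(mdp0)

    g_hi = 1e-4
    while reduction(g_hi) < target_mdp_reduction:
        g_hi *= 2.0
        if g_hi > 1.0:
            raise BracketingError("target reduction unreachable below g = 1 nS/pF")
    g_lo = 0.0
    for _ in range(max_iter):
        g_mid = 0.5 * (g_lo + g_hi)
        red = reduction(g_mid)
        if abs(red - target_mdp_reduction) <= tolerance * target_mdp_reduction:
            return g_mid
        if red < target_mdp_reduction:
            g_lo = g_mid
        else:
            g_hi = g_mid
    raise RuntimeError(
        f"calibration did not converge in {max_iter} bisections "
        f"(bracket [{g_lo:.3g}, {g_hi:.3g}])"
    )


def load_cell_model(spec: str, **kwargs) -> CellModel:
    """Load an external cell model from ``"package.module:factory"``.

    The factory is called with ``**kwargs`` and must return a
    :class:`CellModel`-conformant object. This is the hook for supplying a
    published mouse SAN action-potential model without bundling it here.
    """
    module_path, _, attr = spec.partition(":")
    if not attr:
        raise ValueError("model spec must be 'package.module:factory'")
    factory = getattr(importlib.import_module(module_path), attr)
    model = factory(**kwargs)
    for required in ("state_names", "current_names", "currents", "state_derivatives"):
        if not hasattr(model, required):
            raise TypeError(f"loaded object lacks CellModel attribute {required!r}")
    return model
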