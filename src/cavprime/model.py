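"""Four-voltage-sensor gating model of presynaptic Cav channels.

The channel carries current only when all four of its S4 voltage sensors are
simultaneously in the activated position.  Each sensor activates
independently with an identical probability ``P_s(act)``, so the open
probability is ``P_s(act)**4`` and the steady-state single-sensor activation
is the 0.25th power of the Boltzmann open-probability curve

    P_open(V) = 1 / (1 + exp(-alpha * (V - V_Cav50)))

Sensor kinetics are first order with a voltage-dependent velocity: the
approach to steady state runs at ``k_on * P_s(steady act)`` when activating
and ``k_off * (1 - P_s(steady act))`` when deactivating.  The resulting ODE
is integrated with a forward Euler scheme at a fixed step ``dt``.

The normalized current uses an ohmic driving force,

    I(t) = P_s(act)(t)**4 * (V(t) - E_Ca),

with conductance normalized to 1 and inward current negative; only current
ratios and shapes are meaningful, not absolute amplitudes.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .traces import ConfigurationError, CurrentTrace, UndefinedRatioError, VoltageTrace

__all__ = [
    "CavParams",
    "ChannelState",
    "steady_open_probability",
    "steady_sensor_activation",
    "sensor_velocity",
    "step_sensor",
    "state_occupancies",
    "simulate_current",
    "steady_iv_curve",
    "augmentation_ratio",
    "peak_inward_amplitude",
    "convergence_error",
]

_BINOM4 = np.array([1.0, 4.0, 6.0, 4.0, 1.0])


@dataclass(frozen=True)
class CavParams:
    """Constants of the four-sensor Cav model.

    V_Cav50 : potential of half-maximal channel opening (mV)
    alpha   : steepness of the voltage dependence (per mV)
    k_on    : maximal sensor activation rate constant (per ms)
    k_off   : maximal sensor deactivation rate constant (per ms)
    E_Ca    : Ca++ equilibrium potential (mV)
    dt      : Euler integration step (ms)
    """

    V_Cav50: float = -17.0
    alpha: float = 0.2
    k_on: float = 0.55
    k_off: float = 0.65
    E_Ca: float = 60.0
    dt: float = 0.01

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.k_on <= 0 or self.k_off <= 0:
            raise ValueError("rate constants must be positive")
        if not (0.005 <= self.dt <= 0.05):
            raise ValueError("dt must lie in [0.005, 0.05] ms")
        if self.E_Ca <= self.V_Cav50:
            raise ValueError("E_Ca must exceed V_Cav50")

    def with_rates(self, kon_scale: float = 1.0, koff_scale: float = 1.0) -> "CavParams":
        return replace(self, k_on=self.k_on * kon_scale, k_off=self.k_off * koff_scale)


@dataclass(frozen=True)
class ChannelState:
    """Single-sensor activation probability and 5-state channel occupancy
    (0..4 sensors active; the 4-active state is the open state)."""

    P_s_act: float
    occupancy: np.ndarray

    def __post_init__(self):
        if not 0.0 <= self.P_s_act <= 1.0:
            raise ValueError("P_s_act must lie in [0, 1]")


def _check_prob(p: float, name: str) -> float:
    p = float(p)
    if not (0.0 <= p <= 1.0) or not math.isfinite(p):
        raise ValueError(f"{name} must be a probability in [0, 1]")
    return p


def steady_open_probability(V, params: CavParams = CavParams()):
    """Steady-state open probability at membrane potential ``V`` (mV)."""
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("V must be finite")
    with np.errstate(over="ignore"):  # saturates to 0 for very negative V
        out = 1.0 / (1.0 + np.exp(-params.alpha * (V - params.V_Cav50)))
    return float(out) if out.ndim == 0 else out

def steady_sensor_activation(V, params: CavParams = CavParams()):
    """Steady-state single-sensor activation, the 0.25th power of the
    open-probability curve."""
    return steady_open_probability(V, params) ** 0.25


def sensor_velocity(P_act: float, P_steady: float, params: CavParams = CavParams()) -> float:
    """Rate (per ms) governing the sensor's relaxation toward steady state.

    Activation (P_steady > P_act) runs at k_on * P_steady; deactivation at
    k_off * (1 - P_steady).  At the tie the drive term is zero, so the branch
    choice is immaterial (activation branch returned).
    """
    P_act = _check_prob(P_act, "P_act")
    P_steady = _check_prob(P_steady, "P_steady")
    if P_steady >= P_act:
        return params.k_on * P_steady
    return params.k_off * (1.0 - P_steady)


def step_sensor(P_act: float, V: float, params: CavParams = CavParams()) -> float:
    """One Euler step of the sensor ODE at voltage ``V``; result clipped to [0, 1]."""
    P_act = _check_prob(P_act, "P_act")
    ps = steady_sensor_activation(float(V), params)
    v = sensor_velocity(P_act, ps, params)
    out = P_act + params.dt * v * (ps - P_act)
    return min(max(out, 0.0), 1.0)


def state_occupancies(P_act: float) -> np.ndarray:
    """Occupancies (P_a..P_d, P_open) of the five channel states for a given
    single-sensor activation probability: the binomial(4, P_act) masses."""
    P_act = _check_prob(P_act, "P_act")
    k = np.arange(5)
    return _BINOM4 * P_act**k * (1.0 - P_act) ** (4 - k)


def _integrate(ps_steady: np.ndarray, p0: float, dt: float, k_on: float, k_off: float) -> np.ndarray:
    """Euler trajectory of P_s(act) given the per-sample steady values."""
    out = np.empty_like(ps_steady)
    p = p0
    for i in range(ps_steady.size):
        out[i] = p
        s = ps_steady[i]
        v = k_on * s if s >= p else k_off * (1.0 - s)
        p += dt * v * (s - p)
        if p < 0.0:
            p = 0.0
        elif p > 1.0:
            p = 1.0
    return out


def simulate_current(
    stim: VoltageTrace,
    params: CavParams = CavParams(),
    P_init: float | str = "steady",
):
    """Simulate the normalized Ca++ current driven by a voltage command.

    Parameters
    ----------
    stim : VoltageTrace
        Voltage command; its ``dt`` must equal ``params.dt``.
    P_init : float or "steady"
        Initial single-sensor activation.  ``"steady"`` starts at the
        steady-state value for the first command sample.

    Returns
    -------
    (CurrentTrace, np.ndarray)
        The current trace and the (n_samples, 5) state-occupancy trajectory
        ``(P_a, P_b, P_c, P_d, P_open)``.
    """
    if abs(stim.dt - params.dt) > 1e-12:
        raise ConfigurationError(
            f"stimulus dt ({stim.dt} ms) does not match params.dt ({params.dt} ms)"
        )
    ps_steady = steady_sensor_activation(stim.V, params)
    if isinstance(P_init, str):
        if P_init != "steady":
            raise ValueError("P_init must be a probability or 'steady'")
        p0 = float(ps_steady[0])
    else:
        p0 = _check_prob(P_init, "P_init")
    p_act = _integrate(ps_steady, p0, params.dt, params.k_on, params.k_off)
    I = p_act**4 * (stim.V - params.E_Ca)
    k = np.arange(5)
    occ = _BINOM4 * p_act[:, None] ** k * (1.0 - p_act[:, None]) ** (4 - k)
    return CurrentTrace(stim.t0, stim.dt, I), occ


def steady_iv_curve(V_grid: Sequence[float], params: CavParams = CavParams()) -> np.ndarray:
    """Steady-state I-V relationship: rows of (V, I) with
    I = P_open(V) * (V - E_Ca)."""
    V = np.asarray(V_grid, dtype=float)
    if V.size == 0:
        raise ValueError("V_grid must not be empty")
    if not np.all(np.isfinite(V)):
        raise ValueError("V_grid must be finite")
    I = steady_open_probability(V, params) * (V - params.E_Ca)
    return np.column_stack([V, I])


def peak_inward_amplitude(trace: CurrentTrace, window: tuple[float, float],
                          baseline_ms: float = 5.0) -> float:
    """Baseline-subtracted peak inward amplitude |min(I) - baseline| in a window.

    Baseline is the mean current over ``baseline_ms`` immediately before the
    window start, which makes ratios robust to holding current.
    """
    i0, i1 = trace.index_at(window[0]), trace.index_at(window[1])
    if not (0 <= i0 < i1 <= len(trace)):
        raise ValueError("window outside trace")
    ib = max(0, i0 - int(round(baseline_ms / trace.dt)))
    baseline = float(trace.I[ib:i0].mean()) if i0 > ib else float(trace.I[i0])
    return abs(float(trace.I[i0:i1].min()) - baseline)


def augmentation_ratio(test: CurrentTrace, control: CurrentTrace,
                       window: tuple[float, float]) -> float:
    """Ratio of baseline-subtracted peak inward amplitudes, test / control."""
    if abs(test.dt - control.dt) > 1e-12:
        raise ConfigurationError("test and control traces must share dt")
    a_test = peak_inward_amplitude(test, window)
    a_ctrl = peak_inward_amplitude(control, window)
    if a_ctrl == 0.0:
        raise UndefinedRatioError("control trace has zero peak amplitude")
    return a_test / a_ctrl


def convergence_error(stim: VoltageTrace, params: CavParams = CavParams(),
                      refine: int = 10) -> float:
    """Relative peak-current discrepancy between the configured dt and a
    ``refine``-fold finer Euler step (utility for checking the integration
    error of a protocol)."""
    coarse, _ = simulate_current(stim, params)
    fine_dt = params.dt / refine
    n_fine = (len(stim) - 1) * refine + 1
    V_fine = np.interp(np.arange(n_fine) * fine_dt, stim.t - stim.t0, stim.V)
    fine_params = CavParams(params.V_Cav50, params.alpha, params.k_on,
                            params.k_off, params.E_Ca, max(fine_dt, 0.005))
    # bypass the dt-range guard for the reference run
    object.__setattr__(fine_params, "dt", fine_dt)
    fine, _ = simulate_current(VoltageTrace(stim.t0, fine_dt, V_fine), fine_params)
    peak_f = abs(fine.I.min())
    if peak_f == 0.0:
        return 0.0
    return abs(abs(coarse.I.min()) - peak_f) / peak_f
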