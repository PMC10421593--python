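"""Inverse problems for the four-sensor Cav model.

Fits the steady I-V relationship for (V_Cav50, alpha), the current time
course for (k_on, k_off), the activation time constant of a step response,
and isolates the slow residual (autoreceptor-like) current by amplitude-
matched subtraction of the simulated Ca++ current from a recorded trace.

All fitters use bounded trust-region least squares with a small multi-start
(3 starting points) to avoid the sigmoid's flat directions, and report a
converged flag instead of raising on failure.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .model import CavParams, simulate_current
from .traces import ConfigurationError, CurrentTrace, VoltageTrace

__all__ = [
    "IVDataset",
    "FitResult",
    "fit_iv",
    "fit_kinetics",
    "activation_tau",
    "isolate_autoreceptor",
]

BOUNDS_ALPHA = (0.01, 1.0)
BOUNDS_V50 = (-60.0, 20.0)
BOUNDS_RATE = (0.005, 55.0)


@dataclass
class IVDataset:
    """Measured (V, I) pairs, V strictly increasing; currents normalized."""

    V: np.ndarray
    I: np.ndarray
    spread: np.ndarray | None = None

    def __post_init__(self):
        self.V = np.asarray(self.V, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.V.size < 4:
            raise ValueError("an I-V dataset needs at least 4 points")
        if self.V.size != self.I.size:
            raise ValueError("V and I must have equal length")
        if not np.all(np.diff(self.V) > 0):
            raise ValueError("V must be strictly increasing")


@dataclass
class FitResult:
    params: dict[str, float]
    residual_norm: float
    converged: bool
    stderr: dict[str, float] | None = None
    flags: dict[str, bool] = field(default_factory=dict)
    message: str = ""

    def __getitem__(self, name: str) -> float:
        return self.params[name]


def _boltzmann_iv(V, v50, alpha, scale, e_ca):
    return scale / (1.0 + np.exp(-alpha * (V - v50))) * (V - e_ca)


def fit_iv(data: IVDataset, E_Ca: float = 60.0, weighted: bool = False) -> FitResult:
    """Least-squares fit of scale * P_open(V) * (V - E_Ca) to an I-V dataset.

    E_Ca is held fixed; (V_Cav50, alpha, scale) are free.  The fit is
    invariant to uniform rescaling of the currents (absorbed by ``scale``).
    """
    span = float(np.abs(data.I).max())
    if span == 0.0:
        return FitResult({"V_Cav50": np.nan, "alpha": np.nan, "scale": np.nan},
                         0.0, converged=False, message="all currents are zero")
    sigma = data.spread if (weighted and data.spread is not None) else None
    starts = [(-17.0, 0.2), (-40.0, 0.05), (0.0, 0.5)]
    best = None
    for v50_0, a_0 in starts:
        try:
            popt, pcov = curve_fit(
                lambda V, v50, a, s: _boltzmann_iv(V, v50, a, s, E_Ca),
                data.V, data.I, p0=[v50_0, a_0, span / 80.0],
                sigma=sigma,
                bounds=([BOUNDS_V50[0], BOUNDS_ALPHA[0], 1e-9],
                        [BOUNDS_V50[1], BOUNDS_ALPHA[1], np.inf]),
                maxfev=20000)
        except RuntimeError:
            continue
        rn = float(np.linalg.norm(
            data.I - _boltzmann_iv(data.V, *popt, E_Ca)))
        if best is None or rn < best[0]:
            best = (rn, popt, pcov)
    if best is None:
        return FitResult({"V_Cav50": np.nan, "alpha": np.nan, "scale": np.nan},
                         np.inf, converged=False, message="no start converged")
    rn, popt, pcov = best
    err = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    names = ["V_Cav50", "alpha", "scale"]
    return FitResult(dict(zip(names, map(float, popt))), rn, converged=True,
                     stderr=dict(zip(names, map(float, err))))


def _has_repolarizing_tail(stim: VoltageTrace) -> bool:
    """True when the command returns toward hold after its depolarized phase,
    leaving samples that constrain deactivation."""
    v = stim.V
    i_top = int(np.argmax(v))
    v_hold = v[0]
    after = v[i_top:]
    return bool(np.any(after < v_hold + 0.1 * (v.max() - v_hold))) and v.max() > v_hold


def fit_kinetics(trace: CurrentTrace, stim: VoltageTrace,
                 fixed: dict[str, float] | None = None) -> FitResult:
    """Fit (k_on, k_off, scale) by matching the simulated current to a
    recorded step response; V_Cav50, alpha and E_Ca are held fixed.

    k_on is constrained by the depolarization's rising phase and k_off by the
    repolarizing tail; a command without a tail leaves k_off unidentifiable
    (flagged, not raised).
    """
    fixed = fixed or {}
    if abs(trace.dt - stim.dt) > 1e-12 or len(trace) != len(stim):
        raise ConfigurationError("trace and stimulus must share sampling")
    base = CavParams(
        V_Cav50=fixed.get("V_Cav50", -17.0), alpha=fixed.get("alpha", 0.2),
        E_Ca=fixed.get("E_Ca", 60.0), dt=stim.dt)

    target = trace.I
    span = float(np.abs(target).max())

    def residual(theta):
        kon, koff, scale = theta
        sim, _ = simulate_current(stim, CavParams(
            base.V_Cav50, base.alpha, kon, koff, base.E_Ca, base.dt))
        return (scale * sim.I - target)

    starts = [(0.55, 0.65), (0.1, 0.1), (2.0, 2.0)]
    best = None
    for k0 in starts:
        res = least_squares(
            residual, x0=[k0[0], k0[1], max(span / 40.0, 1e-6)],
            bounds=([BOUNDS_RATE[0], BOUNDS_RATE[0], 1e-9],
                    [BOUNDS_RATE[1], BOUNDS_RATE[1], np.inf]),
            xtol=1e-12, ftol=1e-12)
        if best is None or res.cost < best.cost:
            best = res
    names = ["k_on", "k_off", "scale"]
    flags = {}
    if not _has_repolarizing_tail(stim):
        flags["k_off_unidentifiable"] = True
    return FitResult(dict(zip(names, map(float, best.x))),
                     float(np.sqrt(2.0 * best.cost)),
                     converged=bool(best.success), flags=flags)


def activation_tau(trace: CurrentTrace, window: tuple[float, float] | None = None,
                   baseline_ms: float = 5.0) -> float:
    """Activation time constant: tau of A*(1 - exp(-t/tau)) + B fitted to the
    rising inward current.

    When ``window`` is None it runs from current onset (3x baseline-noise
    crossing, floored at 1% of peak) to 95% of the plateau amplitude.
    """
    I = trace.I
    dt = trace.dt
    if window is None:
        nb = max(2, int(round(baseline_ms / dt)))
        base = I[:nb]
        b0, bsd = float(base.mean()), float(base.std())
        dev = -(I - b0)  # inward deviation, positive
        peak = float(dev.max())
        thr = max(3.0 * bsd, 0.01 * peak)
        i0 = int(np.argmax(dev > thr))
        i1 = int(np.argmax(dev >= 0.95 * peak))
        if i1 <= i0:
            i1 = dev.size - 1
    else:
        i0, i1 = trace.index_at(window[0]), trace.index_at(window[1])
    y = -(I[i0:i1 + 1] - I[max(0, i0 - 1)])
    t = np.arange(y.size) * dt
    drawdown = np.maximum.accumulate(y) - y
    if drawdown.max() > 0.05 * max(np.ptp(y), 1e-12):
        warnings.warn("fit window is not monotonically rising", stacklevel=2)
    p0 = [max(y.max(), 1e-9), max(t[-1] / 3.0, dt), 0.0]
    popt, _ = curve_fit(lambda x, A, tau, B: A * (1 - np.exp(-x / tau)) + B,
                        t, y, p0=p0, maxfev=20000)
    return float(popt[1])


def isolate_autoreceptor(recorded: CurrentTrace, simulated: CurrentTrace,
                         match_ms: float = 5.0):
    """Residual (autoreceptor-like) current: recorded minus amplitude-matched
    simulated Ca++ current.

    The scale factor is a least-squares match over the first ``match_ms`` of
    the depolarization, where the fast Cav component dominates.

    Returns (residual CurrentTrace, fitted scale).
    """
    if abs(recorded.dt - simulated.dt) > 1e-12 or len(recorded) != len(simulated):
        raise ConfigurationError("recorded and simulated traces must share sampling")
    s = simulated.I
    onset_thr = 1e-3 * max(float(np.abs(s - s[0]).max()), 1e-300)
    i0 = int(np.argmax(np.abs(s - s[0]) > onset_thr))
    i1 = min(s.size, i0 + int(round(match_ms / simulated.dt)))
    seg_s = s[i0:i1]
    seg_r = recorded.I[i0:i1]
    denom = float(seg_s @ seg_s)
    scale = float(seg_r @ seg_s) / denom if denom > 0 else 1.0
    residual = recorded.I - scale * s
    return CurrentTrace(recorded.t0, recorded.dt, residual), scale
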