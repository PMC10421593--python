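"""Somato-axonal coupling analysis of paired current-clamp recordings.

Implements the trace-level operators used to quantify analogue signaling:
threshold detection of EPSPs, soma->bouton event matching, the per-event
coupling ratio (peak axonal / peak somatic depolarization), the
cross-correlogram lag, exponential decay fits, the axonal length constant
from coupling-ratio-vs-distance tables, and cell-attached (CA) spike
width/amplitude metrics measured peak to peak.

Detector conventions (the original threshold detector's internals are
unpublished; these defaults are documented, not claimed identical): the
trace is smoothed with a 0.5 ms boxcar; an event's onset is the last sample
below baseline + 0.2*threshold before its peak; baseline is the median of
the 10 ms preceding the onset.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import correlate, correlation_lags, find_peaks

from .fitting import FitResult
from .traces import CurrentTrace, UndefinedCorrelationError, VoltageTrace

__all__ = [
    "EpspEvent",
    "CaSpike",
    "DistanceCrTable",
    "detect_epsps",
    "match_events",
    "coupling_ratio",
    "cross_correlation_lag",
    "fit_decay",
    "fit_length_constant",
    "ca_spike_metrics",
    "dc_coupling_prediction",
]

SMOOTH_MS = 0.5
BASELINE_MS = 10.0
ONSET_FRACTION = 0.2  # onset level = baseline + 0.2 * threshold


@dataclass
class EpspEvent:
    onset_ms: float
    peak_ms: float
    amplitude_mV: float
    rise_10_90_ms: float = np.nan
    decay_tau_ms: float = np.nan

    def __post_init__(self):
        if self.peak_ms <= self.onset_ms:
            raise ValueError("peak must follow onset")


@dataclass
class CaSpike:
    neg_peak_ms: float
    pos_peak_ms: float
    amplitude: float

    @property
    def width_us(self) -> float:
        return (self.pos_peak_ms - self.neg_peak_ms) * 1000.0


@dataclass
class DistanceCrTable:
    """Rows of (distance um, mean coupling ratio, cell id)."""

    distance_um: np.ndarray
    cr: np.ndarray
    cell_id: np.ndarray | None = None

    def __post_init__(self):
        self.distance_um = np.asarray(self.distance_um, dtype=float)
        self.cr = np.asarray(self.cr, dtype=float)
        if self.distance_um.size != self.cr.size:
            raise ValueError("distance and CR columns must match")
        if np.any(self.distance_um <= 0):
            raise ValueError("distances must be positive")

    def to_frame(self) -> pd.DataFrame:
        d = {"distance_um": self.distance_um, "cr": self.cr}
        if self.cell_id is not None:
            d["cell_id"] = self.cell_id
        return pd.DataFrame(d)


def _smooth(x: np.ndarray, dt: float, width_ms: float = SMOOTH_MS) -> np.ndarray:
    n = max(1, int(round(width_ms / dt)))
    if n == 1:
        return x
    kernel = np.ones(n) / n
    return np.convolve(x, kernel, mode="same")


def _local_baseline(sm: np.ndarray, idx: int, dt: float) -> float:
    nb = int(round(BASELINE_MS / dt))
    lo = max(0, idx - nb)
    return float(np.median(sm[lo:idx])) if idx > lo else float(sm[idx])


def _refine_event(sm: np.ndarray, dt: float, t0: float, ipk: int,
                  threshold: float) -> EpspEvent | None:
    # provisional baseline well before the peak, then onset by level crossing,
    # then the definitive baseline from the 10 ms preceding the onset
    nb = int(round(BASELINE_MS / dt))
    lo = max(0, ipk - 2 * nb)
    b0 = float(np.median(sm[lo:ipk])) if ipk > lo else float(sm[ipk])
    level = b0 + ONSET_FRACTION * threshold
    below = np.nonzero(sm[:ipk] < level)[0]
    i_on = int(below[-1]) if below.size else max(0, ipk - nb)
    baseline = _local_baseline(sm, i_on, dt)
    amp = float(sm[ipk] - baseline)
    if amp < threshold or ipk <= i_on:
        return None
    # 10-90% risetime on the rising limb
    rising = sm[i_on:ipk + 1] - baseline
    i10 = int(np.argmax(rising >= 0.1 * amp))
    i90 = int(np.argmax(rising >= 0.9 * amp))
    rise = (i90 - i10) * dt
    return EpspEvent(onset_ms=t0 + i_on * dt, peak_ms=t0 + ipk * dt,
                     amplitude_mV=amp, rise_10_90_ms=rise)


def detect_epsps(trace: VoltageTrace, threshold_mV: float = 3.0,
                 min_separation_ms: float = 5.0,
                 fit_decays: bool = False,
                 decay_tau_guess_ms: float = 20.0) -> list[EpspEvent]:
    """Threshold detection of EPSP-like depolarizing events.

    Events whose baseline-subtracted peak (on the smoothed trace) reaches
    ``threshold_mV``, separated by at least ``min_separation_ms`` (closer
    peaks are merged, keeping the larger).  With ``fit_decays`` each event's
    decay is fitted mono-exponentially from its peak.
    """
    sm = _smooth(trace.V, trace.dt)
    distance = max(1, int(round(min_separation_ms / trace.dt)))
    peaks, _ = find_peaks(sm, prominence=threshold_mV, distance=distance)
    events = []
    for ipk in peaks:
        ev = _refine_event(sm, trace.dt, trace.t0, int(ipk), threshold_mV)
        if ev is None:
            continue
        if fit_decays:
            seg_end = min(len(sm), ipk + int(round(5 * decay_tau_guess_ms / trace.dt)))
            seg = VoltageTrace(0.0, trace.dt, sm[ipk:seg_end])
            try:
                res = fit_decay(seg, n_exp=1)
                ev.decay_tau_ms = res["tau1"]
            except RuntimeError:
                pass
        events.append(ev)
    return events


def match_events(soma_events: list[EpspEvent], bouton_trace: VoltageTrace,
                 search_window_ms: float = 10.0,
                 min_amplitude_mV: float = 1.0):
    """Pair each somatic event with the bouton-trace peak inside
    [onset, onset + window].

    The axonal amplitude uses the same local-baseline convention as the
    detector; windows whose peak stays below ``min_amplitude_mV`` count as
    unmatched.  Returns (pairs, n_unmatched) where each pair is
    (somatic EpspEvent, axonal EpspEvent).
    """
    sm = _smooth(bouton_trace.V, bouton_trace.dt)
    dt = bouton_trace.dt
    pairs = []
    unmatched = 0
    for ev in soma_events:
        i0 = max(0, bouton_trace.index_at(ev.onset_ms))
        i1 = min(len(sm), i0 + int(round(search_window_ms / dt)) + 1)
        if i1 - i0 < 2:
            unmatched += 1
            continue
        ipk = i0 + int(np.argmax(sm[i0:i1]))
        baseline = _local_baseline(sm, i0, dt)
        amp = float(sm[ipk] - baseline)
        if amp < min_amplitude_mV or ipk == i0:
            unmatched += 1
            continue
        ax = EpspEvent(onset_ms=ev.onset_ms, peak_ms=bouton_trace.t0 + ipk * dt,
                       amplitude_mV=amp)
        pairs.append((ev, ax))
    return pairs, unmatched


def coupling_ratio(pairs):
    """Per-event coupling ratios (axonal/somatic amplitude), their mean and SD."""
    if not pairs:
        raise ValueError("at least one matched pair is required")
    crs = []
    for soma_ev, ax_ev in pairs:
        if soma_ev.amplitude_mV == 0:
            warnings.warn("event with zero somatic amplitude excluded", stacklevel=2)
            continue
        crs.append(ax_ev.amplitude_mV / soma_ev.amplitude_mV)
    crs = np.asarray(crs)
    return crs, float(crs.mean()), float(crs.std(ddof=1)) if crs.size > 1 else 0.0


def cross_correlation_lag(soma: VoltageTrace, bouton: VoltageTrace,
                          max_lag_ms: float = 20.0) -> float:
    """Lag (ms) maximizing the normalized cross-correlation of the
    mean-subtracted traces; positive means the bouton lags the soma."""
    if abs(soma.dt - bouton.dt) > 1e-12:
        raise ValueError("traces must share dt")
    a = bouton.V - bouton.V.mean()
    b = soma.V - soma.V.mean()
    if a.std() == 0 or b.std() == 0:
        raise UndefinedCorrelationError("constant trace has no defined correlation")
    cc = correlate(a, b, mode="full")
    lags = correlation_lags(a.size, b.size, mode="full")
    keep = np.abs(lags) <= int(round(max_lag_ms / soma.dt))
    best = lags[keep][np.argmax(cc[keep])]
    return float(best * soma.dt)


def _mono(t, A, tau, C):
    return A * np.exp(-t / tau) + C


def _bi(t, A1, tau1, A2, tau2, C):
    return A1 * np.exp(-t / tau1) + A2 * np.exp(-t / tau2) + C


def fit_decay(segment: VoltageTrace, n_exp: int = 1) -> FitResult:
    """Mono- or bi-exponential least-squares fit of a decaying segment that
    starts at the event peak.  For n_exp=2, tau1 < tau2 by convention; a
    collapsed second component (tau2 ~ tau1 or negligible weight) is flagged
    degenerate."""
    y = segment.V
    t = np.arange(y.size) * segment.dt
    if y[-1] > y[0]:
        warnings.warn("segment does not decay; fit may be meaningless", stacklevel=2)
    amp0 = max(y[0] - y[-1], 1e-9)
    tspan = t[-1] if t[-1] > 0 else 1.0
    if n_exp == 1:
        popt, _ = curve_fit(_mono, t, y, p0=[amp0, tspan / 3.0, y[-1]], maxfev=20000)
        return FitResult({"A1": float(popt[0]), "tau1": float(popt[1]),
                          "C": float(popt[2])},
                         float(np.linalg.norm(y - _mono(t, *popt))), converged=True)
    if n_exp != 2:
        raise ValueError("n_exp must be 1 or 2")
    popt, _ = curve_fit(_bi, t, y,
                        p0=[amp0 / 2, tspan / 10.0, amp0 / 2, tspan / 2.0, y[-1]],
                        maxfev=40000)
    A1, tau1, A2, tau2, C = popt
    if tau1 > tau2:  # enforce tau1 < tau2
        A1, tau1, A2, tau2 = A2, tau2, A1, tau1
    flags = {}
    total = abs(A1) + abs(A2)
    if tau2 / max(tau1, 1e-12) < 1.5 or (total > 0 and abs(A2) / total < 1e-3) \
            or (total > 0 and abs(A1) / total < 1e-3):
        flags["degenerate_second_component"] = True
    return FitResult({"A1": float(A1), "tau1": float(tau1), "A2": float(A2),
                      "tau2": float(tau2), "C": float(C)},
                     float(np.linalg.norm(y - _bi(t, A1, tau1, A2, tau2, C))),
                     converged=True, flags=flags)


def fit_length_constant(table: DistanceCrTable, constrain_A: bool = False,
                        lambda_max_um: float = 1e6) -> FitResult:
    """Exponential length constant of coupling vs distance:
    CR(d) = A * exp(-d / lambda).

    The prefactor A is free by default (dendro-somatic attenuation precedes
    the axon); ``constrain_A`` fixes A = 1.  A fit driven to the lambda bound
    (e.g. distance-independent CR) is flagged unidentifiable.
    """
    d, cr = table.distance_um, table.cr
    if np.unique(d).size < 2:
        raise ValueError("need at least two distinct distances")
    try:
        if constrain_A:
            popt, pcov = curve_fit(lambda x, lam: np.exp(-x / lam), d, cr,
                                   p0=[150.0], bounds=(1.0, lambda_max_um),
                                   maxfev=20000)
            params = {"lambda_um": float(popt[0]), "A": 1.0}
            resid = cr - np.exp(-d / popt[0])
            err = {"lambda_um": float(np.sqrt(max(pcov[0, 0], 0.0)))}
        else:
            popt, pcov = curve_fit(lambda x, A, lam: A * np.exp(-x / lam), d, cr,
                                   p0=[1.0, 150.0],
                                   bounds=([1e-6, 1.0], [10.0, lambda_max_um]),
                                   maxfev=20000)
            params = {"lambda_um": float(popt[1]), "A": float(popt[0])}
            resid = cr - popt[0] * np.exp(-d / popt[1])
            sd = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
            err = {"A": float(sd[0]), "lambda_um": float(sd[1])}
    except RuntimeError as exc:
        return FitResult({"lambda_um": np.nan, "A": np.nan}, np.inf,
                         converged=False, message=str(exc))
    flags = {}
    if params["lambda_um"] > 0.5 * lambda_max_um:
        flags["lambda_unidentifiable"] = True
    return FitResult(params, float(np.linalg.norm(resid)), converged=True,
                     stderr=err, flags=flags)


def ca_spike_metrics(trace: CurrentTrace, threshold: float = 1.0,
                     pos_window_ms: float = 3.0,
                     min_separation_ms: float = 1.0,
                     smooth_ms: float = 0.1) -> list[CaSpike]:
    """Cell-attached spike metrics, measured peak to peak.

    Each spike's negative extremum (maximal rising slope of the intracellular
    AP) is threshold-detected on a lightly smoothed trace; the positive
    extremum is the maximum within ``pos_window_ms`` after it.  Width is the
    time between the extrema (us); amplitude is their value difference
    (baseline-offset invariant).
    """
    dt = trace.dt
    I = _smooth(trace.I, dt, smooth_ms) if smooth_ms > 0 else trace.I
    distance = max(1, int(round(min_separation_ms / dt)))
    base = float(np.median(I))
    neg_peaks, _ = find_peaks(-(I - base), height=threshold, distance=distance)
    spikes = []
    for ineg in neg_peaks:
        i1 = min(I.size, ineg + int(round(pos_window_ms / dt)) + 1)
        if i1 - ineg < 2:
            continue
        ipos = ineg + 1 + int(np.argmax(I[ineg + 1:i1]))
        spikes.append(CaSpike(
            neg_peak_ms=trace.t0 + ineg * dt,
            pos_peak_ms=trace.t0 + ipos * dt,
            amplitude=float(I[ipos] - I[ineg])))
    return spikes


def dc_coupling_prediction(soma_step_mV: float, dc_coupling_ratio: float) -> float:
    """Predicted bouton depolarization for a somatic DC step: the step size
    scaled by the DC coupling ratio."""
    return soma_step_mV * dc_coupling_ratio
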