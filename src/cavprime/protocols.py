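"""Voltage-command construction for the bouton voltage-clamp protocols.

The experiments applied recorded waveforms; here they are synthesized from
their published summary parameters:

* AP: a product of rising and falling sigmoids whose separation is solved
  numerically so that the interval between the maximal rising and falling
  slopes (the cell-attached spike width) matches ``cas_width`` exactly.
* EPSP: a dual-exponential transient whose rise time constant is solved so
  the 10-90% risetime matches the stated value; the second EPSP superposes
  linearly on the first's decay and is rescaled so both stated peak
  potentials are honored exactly.
* Pre-pulse protocols: piecewise-constant hold / pre-pulse / gap / test
  steps.

All builders are pure functions of their specs and return traces sampled at
``params.dt`` that begin and end at the stated holding potential.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model import CavParams, augmentation_ratio, simulate_current
from .traces import ConfigurationError, FitFailureError, VoltageTrace

__all__ = [
    "ApWaveformSpec",
    "EpspApSpec",
    "PrepulseSpec",
    "build_ap_waveform",
    "build_epsp_ap_waveform",
    "build_prepulse_protocol",
    "run_sweep",
    "epsp_kernel",
    "SWEEP_FAMILIES",
]

AP_THRESHOLD_MV = -40.0  # conventional spike threshold; EPSP peaks must stay below


@dataclass(frozen=True)
class ApWaveformSpec:
    """Stylized axonal AP: rest -70 mV, peak +40 mV, width 780 us between
    maximal rising and falling slopes (the cell-attached spike width)."""

    V_rest: float = -70.0
    V_peak: float = 40.0
    cas_width_us: float = 780.0
    rise_tau: float = 0.15  # ms; max rise slope ~ amplitude/(4*rise_tau)
    decay_tau: float = 0.40  # ms
    pre_ms: float = 5.0     # baseline before AP onset
    post_ms: float = 5.0    # baseline after repolarization

    def __post_init__(self):
        if self.V_peak <= self.V_rest:
            raise ValueError("V_peak must exceed V_rest")
        if self.cas_width_us <= 0:
            raise ValueError("cas_width_us must be positive")


@dataclass(frozen=True)
class EpspApSpec:
    """An AP preceded by two subthreshold EPSPs.

    ``epsp_peaks`` are absolute peak potentials (mV); ``lead_time_ms`` is the
    interval from the first EPSP's onset to the AP's onset.  EPSP kinetics
    default to the axonal EPSP values (10-90% rise 5.7 ms, decay tau 20.4 ms).
    """

    ap: ApWaveformSpec = field(default_factory=ApWaveformSpec)
    epsp_peaks: tuple[float, ...] = (-58.0, -53.0)
    epsp_interval_ms: float = 19.5
    lead_time_ms: float = 40.0
    epsp_rise_10_90_ms: float = 5.7
    epsp_decay_tau_ms: float = 20.4
    interval_before_ap_ms: float = 0.0  # rest inserted between EPSPs and AP
    tail_ms: float = 15.0

    def __post_init__(self):
        if self.lead_time_ms <= self.epsp_interval_ms:
            raise ValueError("lead_time_ms must exceed epsp_interval_ms")
        for p in self.epsp_peaks:
            if p < self.ap.V_rest:
                raise ValueError("EPSP peaks must not lie below V_rest")


@dataclass(frozen=True)
class PrepulseSpec:
    """Hold -> subthreshold pre-pulse -> (gap at hold) -> test pulse -> hold."""

    hold_V: float = -70.0
    pre_V: float = -50.0
    pre_dur_ms: float = 20.0
    gap_ms: float = 0.0
    test_V: float = 30.0
    test_dur_ms: float = 1.5
    pre_hold_ms: float = 10.0
    tail_ms: float = 10.0

    def __post_init__(self):
        if min(self.pre_dur_ms, self.gap_ms, self.test_dur_ms) < 0:
            raise ValueError("durations must be non-negative")


def _ap_shape(t: np.ndarray, t_peak: float, sep: float, tr: float, td: float) -> np.ndarray:
    rise = 1.0 / (1.0 + np.exp(-(t - (t_peak - sep / 2.0)) / tr))
    fall = 1.0 / (1.0 + np.exp((t - (t_peak + sep / 2.0)) / td))
    return rise * fall


def _ap_segment(spec: ApWaveformSpec, dt: float) -> tuple[np.ndarray, int]:
    """AP samples (baseline-padded) and the index of the AP onset, defined as
    the first sample exceeding V_rest by 1% of the AP amplitude."""
    width_ms = spec.cas_width_us / 1000.0
    t_peak = spec.pre_ms + width_ms + 6.0 * spec.rise_tau
    dur = t_peak + width_ms + 8.0 * spec.decay_tau + spec.post_ms
    t = np.arange(0.0, dur, dt)

    def width_error(sep: float) -> float:
        g = _ap_shape(t, t_peak, sep, spec.rise_tau, spec.decay_tau)
        dg = np.gradient(g, dt)
        return (t[np.argmin(dg)] - t[np.argmax(dg)]) - width_ms

    lo, hi = 0.02, width_ms + 10.0 * (spec.rise_tau + spec.decay_tau)
    try:
        sep = brentq(width_error, lo, hi, xtol=1e-6)
    except ValueError as exc:
        raise FitFailureError(
            f"shape constants (rise_tau={spec.rise_tau}, decay_tau={spec.decay_tau}) "
            f"cannot produce a {spec.cas_width_us} us slope separation"
        ) from exc
    g = _ap_shape(t, t_peak, sep, spec.rise_tau, spec.decay_tau)
    g /= g.max()
    V = spec.V_rest + (spec.V_peak - spec.V_rest) * g
    onset = int(np.argmax(g > 0.01))
    return V, onset


def build_ap_waveform(spec: ApWaveformSpec = ApWaveformSpec(),
                      params: CavParams = CavParams()) -> VoltageTrace:
    """Single stylized AP on a resting baseline."""
    V, _ = _ap_segment(spec, params.dt)
    return VoltageTrace(0.0, params.dt, V)


def epsp_kernel(dt: float, rise_10_90_ms: float, decay_tau_ms: float,
                dur_ms: float = 150.0) -> np.ndarray:
    """Unit-peak dual-exponential EPSP kernel whose 10-90% risetime equals
    ``rise_10_90_ms`` (rise time constant solved numerically)."""
    t = np.arange(0.0, dur_ms, dt)

    def rise_error(tau_r: float) -> float:
        k = np.exp(-t / decay_tau_ms) - np.exp(-t / tau_r)
        ipk = int(np.argmax(k))
        k = k / k[ipk]
        rising = k[: ipk + 1]
        i10 = int(np.searchsorted(rising, 0.1))
        i90 = int(np.searchsorted(rising, 0.9))
        return (i90 - i10) * dt - rise_10_90_ms

    try:
        tau_r = brentq(rise_error, 2.0 * dt, decay_tau_ms * 0.999, xtol=1e-8)
    except ValueError as exc:
        raise FitFailureError(
            f"no dual-exponential rise constant gives a {rise_10_90_ms} ms "
            f"10-90% risetime with decay tau {decay_tau_ms} ms"
        ) from exc
    k = np.exp(-t / decay_tau_ms) - np.exp(-t / tau_r)
    return k / k.max()


def _epsp_composite(spec: EpspApSpec, dt: float, n: int, i_first: int) -> np.ndarray:
    """Summed EPSP deviation from rest (mV, >= 0), peaks honored exactly."""
    kernel = epsp_kernel(dt, spec.epsp_rise_10_90_ms, spec.epsp_decay_tau_ms)
    comp = np.zeros(n)
    rest = spec.ap.V_rest
    onsets = [i_first + int(round(j * spec.epsp_interval_ms / dt))
              for j in range(len(spec.epsp_peaks))]
    for onset, peak_V in zip(onsets, spec.epsp_peaks):
        target = peak_V - rest
        if target == 0.0:
            continue
        seg_len = min(kernel.size, n - onset)

        def overshoot(a: float, _onset=onset, _len=seg_len, _target=target) -> float:
            trial = comp.copy()
            trial[_onset:_onset + _len] += a * kernel[:_len]
            return trial[_onset:].max() - _target

        try:
            amp = brentq(overshoot, 1e-9, 10.0 * abs(target), xtol=1e-10)
        except ValueError as exc:
            raise FitFailureError(
                f"cannot honor EPSP peak at {peak_V} mV given the preceding "
                f"transients") from exc
        comp[onset:onset + seg_len] += amp * kernel[:seg_len]
    return comp


def build_epsp_ap_waveform(spec: EpspApSpec = EpspApSpec(),
                           params: CavParams = CavParams(),
                           include_control: bool = False):
    """AP preceded by two EPSPs (optionally also the matched AP-alone control).

    The AP onset falls exactly ``lead_time_ms`` after the first EPSP onset;
    an optional rest interval (``interval_before_ap_ms``) truncates the EPSP
    tail that many ms before the AP.  Test and control share the identical AP
    segment (spliced by elementwise max with the subthreshold envelope).
    """
    dt = params.dt
    ap_seg, ap_onset_idx = _ap_segment(spec.ap, dt)
    i_first = int(round(spec.ap.pre_ms / dt))
    i_ap_onset = i_first + int(round(spec.lead_time_ms / dt))
    n = i_ap_onset + (ap_seg.size - ap_onset_idx) + int(round(spec.tail_ms / dt))

    comp = _epsp_composite(spec, dt, n, i_first)
    if comp.max() + spec.ap.V_rest > AP_THRESHOLD_MV:
        warnings.warn("EPSP summation exceeds AP threshold; waveform is no "
                      "longer subthreshold", stacklevel=2)
    if spec.interval_before_ap_ms > 0:
        i_cut = i_ap_onset - int(round(spec.interval_before_ap_ms / dt))
        comp[max(i_cut, 0):] = 0.0

    ap_full = np.full(n, spec.ap.V_rest)
    i_start = i_ap_onset - ap_onset_idx
    seg = ap_seg[max(0, -i_start): n - i_start]
    ap_full[max(i_start, 0): max(i_start, 0) + seg.size] = seg

    test = VoltageTrace(0.0, dt, np.maximum(spec.ap.V_rest + comp, ap_full))
    if include_control:
        return test, VoltageTrace(0.0, dt, ap_full)
    return test


def build_prepulse_protocol(spec: PrepulseSpec = PrepulseSpec(),
                            params: CavParams = CavParams()) -> VoltageTrace:
    """Piecewise-constant pre-pulse/test protocol."""
    dt = params.dt
    pieces = [
        (spec.pre_hold_ms, spec.hold_V),
        (spec.pre_dur_ms, spec.pre_V),
        (spec.gap_ms, spec.hold_V),
        (spec.test_dur_ms, spec.test_V),
        (spec.tail_ms, spec.hold_V),
    ]
    V = np.concatenate([np.full(int(round(d / dt)), v) for d, v in pieces if d > 0])
    return VoltageTrace(0.0, dt, V)


def _epsp_pair_ratio(spec: EpspApSpec, params: CavParams,
                     window_ms: float = 10.0) -> float:
    test, ctrl = build_epsp_ap_waveform(spec, params, include_control=True)
    I_test, _ = simulate_current(test, params)
    I_ctrl, _ = simulate_current(ctrl, params)
    t_on = spec.ap.pre_ms + spec.lead_time_ms
    return augmentation_ratio(I_test, I_ctrl, (t_on, t_on + window_ms))


def _prepulse_pair_ratio(spec: PrepulseSpec, params: CavParams) -> float:
    test = build_prepulse_protocol(spec, params)
    ctrl = build_prepulse_protocol(replace(spec, pre_V=spec.hold_V), params)
    t_on = spec.pre_hold_ms + spec.pre_dur_ms + spec.gap_ms
    window = (t_on, t_on + spec.test_dur_ms + 5.0)
    I_test, _ = simulate_current(test, params)
    I_ctrl, _ = simulate_current(ctrl, params)
    return augmentation_ratio(I_test, I_ctrl, window)


SWEEP_FAMILIES = ("epsp_interval", "pre_voltage", "pre_duration", "gap",
                  "kon_scale", "koff_scale")


def run_sweep(family: str, values: Sequence[float], base_spec=None,
              params: CavParams = CavParams()) -> pd.DataFrame:
    """Augmentation-ratio sweep over one protocol or kinetic parameter.

    Families
    --------
    epsp_interval : rest interval (ms) inserted between the EPSPs and the AP
                    (base_spec: EpspApSpec)
    pre_voltage   : pre-pulse potential (mV)      (base_spec: PrepulseSpec)
    pre_duration  : pre-pulse duration (ms)       (base_spec: PrepulseSpec)
    gap           : pre-pulse-to-test gap (ms)    (base_spec: PrepulseSpec)
    kon_scale / koff_scale : fold-change of the rate constant, evaluated on
                    the base pre-pulse protocol   (base_spec: PrepulseSpec)

    Returns a DataFrame of (value, ratio) rows in input order.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("sweep values must be finite")
    if family not in SWEEP_FAMILIES:
        raise ConfigurationError(f"unknown sweep family {family!r}; "
                                 f"expected one of {SWEEP_FAMILIES}")
    rows = []
    for v in values:
        if family == "epsp_interval":
            spec = base_spec if base_spec is not None else EpspApSpec()
            r = _epsp_pair_ratio(replace(spec, interval_before_ap_ms=float(v)), params)
        else:
            spec = base_spec if base_spec is not None else PrepulseSpec()
            if family == "pre_voltage":
                r = _prepulse_pair_ratio(replace(spec, pre_V=float(v)), params)
            elif family == "pre_duration":
                r = _prepulse_pair_ratio(replace(spec, pre_dur_ms=float(v)), params)
            elif family == "gap":
                r = _prepulse_pair_ratio(replace(spec, gap_ms=float(v)), params)
            elif family == "kon_scale":
                r = _prepulse_pair_ratio(spec, params.with_rates(kon_scale=float(v)))
            else:  # koff_scale
                r = _prepulse_pair_ratio(spec, params.with_rates(koff_scale=float(v)))
        rows.append((float(v), r))
    return pd.DataFrame(rows, columns=["value", "ratio"])
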