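"""Seeded generators for every input class the analysis pipeline consumes.

The paired-trace generator emulates the paired soma/bouton current-clamp
recordings: Poisson-timed EPSPs, somatic amplitudes drawn from a truncated
Gaussian, and a phenomenological axonal channel (per-event amplitude scaled
by the true coupling ratio, shifted by the programmed lag, slower rise,
shared slow decay) plus additive Gaussian noise.  It is not a cable solve --
it reproduces the statistical structure the analyses assume (attenuation,
lag, risetime slowing, shared tau), not cable physics.

All generators take a single integer seed, are bit-reproducible, and return
their ground truth alongside the data.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal
import warnings

import numpy as np
import pandas as pd

from .coupling import DistanceCrTable
from .model import CavParams, simulate_current
from .protocols import epsp_kernel
from .traces import CurrentTrace, PairedRecording, VoltageTrace

__all__ = [
    "PairGeneratorSpec",
    "NoiseSpec",
    "generate_paired_traces",
    "generate_cr_distance_table",
    "generate_noisy_ica",
    "generate_ca_spike_train",
]


@dataclass(frozen=True)
class NoiseSpec:
    kind: Literal["gaussian-additive", "multiplicative-CV"] = "gaussian-additive"
    level: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.level < 0:
            raise ValueError("noise level must be non-negative")


@dataclass(frozen=True)
class PairGeneratorSpec:
    """Defaults mirror the example paired recording: 29 events in 50 s,
    somatic amplitude 13.1 +/- 2.0 mV, coupling ratio 0.6, lag 2.33 ms,
    somatic rise 1.8 ms / axonal rise 5.7 ms (10-90%), decays 19.9 and
    20.4 ms, resting potential -70 mV."""

    duration_s: float = 50.0
    event_rate_Hz: float = 29.0 / 50.0
    somatic_amp_mean_mV: float = 13.1
    somatic_amp_sd_mV: float = 2.0
    cr_true: float = 0.6
    lag_ms: float = 2.33
    somatic_rise_10_90_ms: float = 1.8
    somatic_decay_tau_ms: float = 19.9
    axonal_rise_10_90_ms: float = 5.7
    axonal_decay_tau_ms: float = 20.4
    noise_sd_mV: float = 0.5
    v_rest_mV: float = -70.0
    distance_um: float = 112.0
    dt_ms: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.cr_true <= 1:
            raise ValueError("cr_true must lie in (0, 1]")
        for k in ("somatic_rise_10_90_ms", "somatic_decay_tau_ms",
                  "axonal_rise_10_90_ms", "axonal_decay_tau_ms"):
            if getattr(self, k) <= 0:
                raise ValueError(f"{k} must be positive")


def _poisson_times(rng: np.random.Generator, rate_hz: float,
                   duration_ms: float, margin_ms: float) -> np.ndarray:
    """Homogeneous Poisson event times (ms) inside [margin, duration - margin]."""
    lo, hi = margin_ms, duration_ms - margin_ms
    times = []
    t = lo
    while True:
        t += rng.exponential(1000.0 / rate_hz)
        if t >= hi:
            break
        times.append(t)
    return np.asarray(times)


def generate_paired_traces(spec: PairGeneratorSpec = PairGeneratorSpec()):
    """Synthetic paired soma/bouton recording.

    Returns (PairedRecording, truth DataFrame) where the truth table has one
    row per programmed event: onset_ms, somatic/axonal peak amplitude, cr.
    """
    rng = np.random.default_rng(spec.seed)
    dur_ms = spec.duration_s * 1000.0
    n = int(round(dur_ms / spec.dt_ms))
    if spec.event_rate_Hz * spec.duration_s < 1:
        warnings.warn("fewer than one event expected on average", stacklevel=2)
    onsets = _poisson_times(rng, spec.event_rate_Hz, dur_ms, margin_ms=100.0)

    k_soma = epsp_kernel(spec.dt_ms, spec.somatic_rise_10_90_ms,
                         spec.somatic_decay_tau_ms)
    k_ax = epsp_kernel(spec.dt_ms, spec.axonal_rise_10_90_ms,
                       spec.axonal_decay_tau_ms)
    soma = np.full(n, spec.v_rest_mV)
    bouton = np.full(n, spec.v_rest_mV)
    lag_idx = int(round(spec.lag_ms / spec.dt_ms))
    rows = []
    for t_on in onsets:
        amp = rng.normal(spec.somatic_amp_mean_mV, spec.somatic_amp_sd_mV)
        while amp <= 0:  # truncate at zero
            amp = rng.normal(spec.somatic_amp_mean_mV, spec.somatic_amp_sd_mV)
        i_on = int(round(t_on / spec.dt_ms))
        seg = min(k_soma.size, n - i_on)
        soma[i_on:i_on + seg] += amp * k_soma[:seg]
        i_ax = i_on + lag_idx
        seg_ax = min(k_ax.size, n - i_ax)
        if seg_ax > 0:
            bouton[i_ax:i_ax + seg_ax] += amp * spec.cr_true * k_ax[:seg_ax]
        rows.append((t_on, amp, amp * spec.cr_true, spec.cr_true))
    if spec.noise_sd_mV > 0:
        soma = soma + rng.normal(0.0, spec.noise_sd_mV, n)
        bouton = bouton + rng.normal(0.0, spec.noise_sd_mV, n)
    truth = pd.DataFrame(rows, columns=["onset_ms", "soma_amp_mV",
                                        "bouton_amp_mV", "cr"])
    pair = PairedRecording(
        soma=VoltageTrace(0.0, spec.dt_ms, soma),
        bouton=VoltageTrace(0.0, spec.dt_ms, bouton),
        distance_um=spec.distance_um)
    return pair, truth


def generate_cr_distance_table(lambda_um: float = 181.0, A: float = 1.0,
                               n_cells: int = 25,
                               d_range_um: tuple[float, float] = (64.5, 244.0),
                               noise: NoiseSpec = NoiseSpec("multiplicative-CV", 0.15)):
    """Coupling-ratio vs distance table: CR = A * exp(-d/lambda) with
    multiplicative (CV) or additive noise.  Returns (DistanceCrTable, truth
    dict)."""
    if n_cells < 2:
        raise ValueError("need at least two cells")
    rng = np.random.default_rng(noise.seed)
    d = rng.uniform(d_range_um[0], d_range_um[1], n_cells)
    d.sort()
    cr = A * np.exp(-d / lambda_um)
    if noise.level > 0:
        if noise.kind == "multiplicative-CV":
            cr = cr * (1.0 + rng.normal(0.0, noise.level, n_cells))
        else:
            cr = cr + rng.normal(0.0, noise.level, n_cells)
    table = DistanceCrTable(d, cr, cell_id=np.arange(n_cells))
    return table, {"lambda_um": lambda_um, "A": A}


def generate_noisy_ica(params: CavParams, stim: VoltageTrace,
                       noise: NoiseSpec = NoiseSpec(),
                       noise_frac_of_peak: float | None = None,
                       slow_transient: tuple[float, float] | None = None):
    """Noisy simulated Ca++ current.

    ``noise_frac_of_peak`` overrides the absolute noise level with a fraction
    of the noiseless peak inward amplitude.  ``slow_transient = (amp, tau)``
    adds a slow exponential (autoreceptor-like) inward component starting at
    the depolarization onset, for testing the subtraction-based isolation.

    Returns (CurrentTrace, truth dict with the clean current).
    """
    clean, _ = simulate_current(stim, params)
    I = clean.I.copy()
    truth = {"clean": clean}
    if slow_transient is not None:
        amp, tau = slow_transient
        i0 = int(np.argmax(np.abs(stim.V - stim.V[0]) > 1e-9))
        t = np.arange(I.size - i0) * stim.dt
        extra = np.zeros_like(I)
        extra[i0:] = -amp * (1.0 - np.exp(-t / tau))
        I = I + extra
        truth["transient"] = CurrentTrace(stim.t0, stim.dt, extra)
    rng = np.random.default_rng(noise.seed)
    sd = noise.level
    if noise_frac_of_peak is not None:
        sd = noise_frac_of_peak * abs(clean.I.min())
    if sd > 0:
        I = I + rng.normal(0.0, sd, I.size)
    return CurrentTrace(stim.t0, stim.dt, I), truth


def generate_ca_spike_train(width_us: float = 620.0, amplitude: float = 10.0,
                            rate_Hz: float = 50.0, duration_s: float = 1.0,
                            noise_sd: float = 0.0, seed: int = 0,
                            dt_ms: float = 0.02, jitter_cv: float = 0.02):
    """Train of biphasic cell-attached spike currents (driven firing).

    Spike times are quasi-regular at ``rate_Hz`` (Gaussian timing jitter of
    ``jitter_cv`` of the interval), emulating current-step-driven firing.
    Each spike is a pair of opposite-polarity Gaussian lobes whose extrema
    are ``width_us`` apart (negative lobe first); peak-to-peak amplitude is
    ``amplitude``.  Returns (CurrentTrace, truth DataFrame of spike times).
    """
    width_ms = width_us / 1000.0
    if width_ms <= 2 * dt_ms:
        raise ValueError("width must exceed two sample intervals")
    rng = np.random.default_rng(seed)
    dur_ms = duration_s * 1000.0
    n = int(round(dur_ms / dt_ms))
    I = np.zeros(n)
    sigma = width_ms / 4.0
    half = amplitude / 2.0
    tk = np.arange(-4 * sigma, width_ms + 4 * sigma, dt_ms)
    kernel = (-half * np.exp(-0.5 * (tk / sigma) ** 2)
              + half * np.exp(-0.5 * ((tk - width_ms) / sigma) ** 2))
    margin = 2.0 + width_ms
    interval = 1000.0 / rate_Hz
    times = np.arange(margin, dur_ms - margin, interval)
    times = times + rng.normal(0.0, jitter_cv * interval, times.size)
    # enforce separation so neighbouring spikes do not distort the extrema
    keep, last = [], -np.inf
    for t in np.sort(times):
        if t - last >= 2.5 * width_ms:
            keep.append(t)
            last = t
    rows = []
    for t_neg in keep:
        i0 = int(round((t_neg - 4 * sigma) / dt_ms))
        seg = min(kernel.size, n - i0)
        if i0 < 0 or seg <= 0:
            continue
        I[i0:i0 + seg] += kernel[:seg]
        rows.append((t_neg, width_us, amplitude))
    if noise_sd > 0:
        I = I + rng.normal(0.0, noise_sd, n)
    truth = pd.DataFrame(rows, columns=["neg_peak_ms", "width_us", "amplitude"])
    return CurrentTrace(0.0, dt_ms, I), truth
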