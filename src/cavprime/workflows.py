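"""End-to-end computations shared by the analysis drivers, the acceptance
script and the acceptance tests.

Each function runs one complete study computation from scratch: stimulus
construction -> simulation -> measurement, or generation -> analysis ->
recovery, and returns plain numbers.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from .coupling import coupling_ratio, detect_epsps, fit_length_constant, match_events
from .fitting import activation_tau, fit_kinetics
from .model import CavParams, augmentation_ratio, simulate_current
from .protocols import EpspApSpec, PrepulseSpec, build_epsp_ap_waveform, \
    build_prepulse_protocol
from .synth import NoiseSpec, PairGeneratorSpec, generate_cr_distance_table, \
    generate_noisy_ica, generate_paired_traces

__all__ = [
    "epsp_priming_augmentation",
    "step_activation_tau",
    "lambda_recovery_median",
    "cr_recovery_mean",
    "kon_recovery_median",
    "canonical_step",
]


def canonical_step(params: CavParams = CavParams(), step_V: float = 0.0,
                   dur_ms: float = 20.0):
    """-70 mV hold -> step -> -70 mV command at params.dt."""
    spec = PrepulseSpec(hold_V=-70.0, pre_V=-70.0, pre_dur_ms=0.0, gap_ms=0.0,
                        test_V=step_V, test_dur_ms=dur_ms, pre_hold_ms=10.0,
                        tail_ms=10.0)
    return build_prepulse_protocol(spec, params)


def epsp_priming_augmentation(params: CavParams = CavParams(),
                              spec: EpspApSpec = EpspApSpec()) -> float:
    """Fold-increase of the AP-evoked peak Ca++ current when the AP is
    preceded by two subthreshold EPSPs (vs the identical AP alone)."""
    test, ctrl = build_epsp_ap_waveform(spec, params, include_control=True)
    I_test, _ = simulate_current(test, params)
    I_ctrl, _ = simulate_current(ctrl, params)
    t_on = spec.ap.pre_ms + spec.lead_time_ms
    return augmentation_ratio(I_test, I_ctrl, (t_on, t_on + 10.0))


def step_activation_tau(params: CavParams = CavParams()) -> float:
    """Single-exponential activation time constant (ms) of the current evoked
    by a -70 -> 0 mV, 20 ms step."""
    stim = canonical_step(params)
    current, _ = simulate_current(stim, params)
    return activation_tau(current)


def lambda_recovery_median(n_replicates: int = 200, seed: int = 0,
                           lambda_true: float = 181.0,
                           n_cells: int = 25, cv: float = 0.15) -> float:
    """Median fitted length constant (um) over seeded replicates of the
    coupling-ratio-vs-distance experiment."""
    rng_seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    est = []
    for s in rng_seeds:
        table, _ = generate_cr_distance_table(
            lambda_um=lambda_true, n_cells=n_cells,
            noise=NoiseSpec("multiplicative-CV", cv, seed=int(s)))
        res = fit_length_constant(table)
        if res.converged:
            est.append(res["lambda_um"])
    return float(np.median(est))


def cr_recovery_mean(seed: int = 0, threshold_mV: float = 3.0,
                     window_ms: float = 10.0) -> tuple[float, int]:
    """Mean per-event coupling ratio recovered by the detection -> matching ->
    ratio pipeline from a synthetic paired recording with the example-cell
    statistics.  Returns (mean CR, number of matched events)."""
    spec = dataclasses.replace(PairGeneratorSpec(), seed=seed)
    pair, _ = generate_paired_traces(spec)
    events = detect_epsps(pair.soma, threshold_mV=threshold_mV)
    pairs, _ = match_events(events, pair.bouton, search_window_ms=window_ms)
    _, mean, _ = coupling_ratio(pairs)
    return mean, len(pairs)


def kon_recovery_median(n_replicates: int = 50, seed: int = 0,
                        noise_frac: float = 0.02) -> float:
    """Median fitted k_on (/ms) from noisy model-generated step responses."""
    params = CavParams()
    stim = canonical_step(params)
    rng_seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    est = []
    for s in rng_seeds:
        trace, _ = generate_noisy_ica(params, stim, NoiseSpec(seed=int(s)),
                                      noise_frac_of_peak=noise_frac)
        res = fit_kinetics(trace, stim)
        if res.converged:
            est.append(res["k_on"])
    return float(np.median(est))
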