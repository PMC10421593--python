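"""Trace-analysis operator tests: detection, matching, coupling ratio, lag,
decay fits, length constant, CA-spike metrics."""
import dataclasses

import numpy as np
import pytest

from cavprime import (CaSpike, CurrentTrace, DistanceCrTable,
                      UndefinedCorrelationError, VoltageTrace, ca_spike_metrics,
                      coupling_ratio, cross_correlation_lag, dc_coupling_prediction,
                      detect_epsps, epsp_kernel, fit_decay, fit_length_constant,
                      match_events)
from cavprime.coupling import EpspEvent

DT = 0.1  # ms, current-clamp sampling used throughout these tests


def train_trace(n_events=29, amp=13.1, duration_ms=50_000.0, rise=1.8,
                decay=19.9, v_rest=-70.0, noise_sd=0.0, seed=0, dt=DT):
    """Evenly spaced EPSP train (plus optional noise)."""
    rng = np.random.default_rng(seed)
    n = int(duration_ms / dt)
    V = np.full(n, v_rest)
    k = epsp_kernel(dt, rise, decay)
    spacing = duration_ms / (n_events + 1)
    onsets = []
    for j in range(n_events):
        i0 = int(round((j + 0.5) * spacing / dt))
        seg = min(k.size, n - i0)
        V[i0:i0 + seg] += amp * k[:seg]
        onsets.append(i0 * dt)
    if noise_sd > 0:
        V = V + rng.normal(0, noise_sd, n)
    return VoltageTrace(0.0, dt, V), onsets


class TestDetectEpsps:
    def test_flat_noise_below_threshold(self):
        rng = np.random.default_rng(1)
        tr = VoltageTrace(0.0, DT, -70.0 + rng.normal(0, 0.3, 100_000))
        assert detect_epsps(tr, threshold_mV=3.0) == []

    def test_counts_full_train(self):
        tr, _ = train_trace(n_events=29, noise_sd=0.3)
        events = detect_epsps(tr, threshold_mV=3.0)
        assert len(events) == 29

    def test_amplitude_and_risetime_recovered(self):
        tr, _ = train_trace(n_events=5, noise_sd=0.0)
        events = detect_epsps(tr, threshold_mV=3.0)
        for ev in events:
            assert ev.amplitude_mV == pytest.approx(13.1, rel=0.05)
            assert ev.rise_10_90_ms == pytest.approx(1.8, abs=0.5)

    def test_close_events_merged(self):
        dt = DT
        n = int(2000 / dt)
        V = np.full(n, -70.0)
        k = epsp_kernel(dt, 1.8, 19.9)
        for onset in (1000.0, 1001.0):  # 1 ms apart
            i0 = int(onset / dt)
            V[i0:i0 + k.size] += 10.0 * k[: n - i0]
        events = detect_epsps(VoltageTrace(0.0, dt, V), threshold_mV=3.0,
                              min_separation_ms=5.0)
        assert len(events) == 1

    def test_decay_fit_on_events(self):
        tr, _ = train_trace(n_events=3, noise_sd=0.0)
        events = detect_epsps(tr, threshold_mV=3.0, fit_decays=True)
        for ev in events:
            assert ev.decay_tau_ms == pytest.approx(19.9, rel=0.1)


class TestMatchAndCouplingRatio:
    def test_identical_traces_zero_lag(self):
        tr, _ = train_trace(n_events=10)
        events = detect_epsps(tr, threshold_mV=3.0)
        pairs, unmatched = match_events(events, tr, search_window_ms=10.0)
        assert unmatched == 0
        for s, a in pairs:
            assert a.peak_ms == pytest.approx(s.peak_ms, abs=2 * DT)
            assert a.amplitude_mV / s.amplitude_mV == pytest.approx(1.0, abs=0.02)

    def test_programmed_lag_recovered(self):
        # same kinetics in both channels, bouton = scaled soma shifted 2.33 ms
        tr, _ = train_trace(n_events=10)
        shift = int(round(2.33 / DT))
        v = np.full_like(tr.V, -70.0)
        v[shift:] = -70.0 + 0.6 * (tr.V[:-shift] + 70.0)
        bouton = VoltageTrace(0.0, DT, v)
        events = detect_epsps(tr, threshold_mV=3.0)
        pairs, _ = match_events(events, bouton, search_window_ms=10.0)
        lags = [a.peak_ms - s.peak_ms for s, a in pairs]
        assert np.median(lags) == pytest.approx(2.33, abs=2 * DT)

    def test_flat_bouton_all_unmatched(self):
        tr, _ = train_trace(n_events=8)
        flat = VoltageTrace(0.0, DT, np.full(len(tr), -70.0))
        events = detect_epsps(tr, threshold_mV=3.0)
        pairs, unmatched = match_events(events, flat, search_window_ms=10.0)
        assert pairs == [] and unmatched == len(events)

    def test_cr_of_example_amplitudes(self):
        s = EpspEvent(onset_ms=0.0, peak_ms=3.0, amplitude_mV=13.1)
        a = EpspEvent(onset_ms=0.0, peak_ms=5.0, amplitude_mV=7.8)
        crs, mean, sd = coupling_ratio([(s, a)])
        assert mean == pytest.approx(0.60, abs=0.01)

    def test_gain_and_offset_invariance(self):
        tr, _ = train_trace(n_events=10)
        shift = int(round(2.0 / DT))
        v = np.full_like(tr.V, -70.0)
        v[shift:] = -70.0 + 0.6 * (tr.V[:-shift] + 70.0)
        bouton = VoltageTrace(0.0, DT, v)

        def pipeline(soma, ax):
            ev = detect_epsps(soma, threshold_mV=3.0)
            pairs, _ = match_events(ev, ax, search_window_ms=10.0)
            crs, mean, _ = coupling_ratio(pairs)
            lag = cross_correlation_lag(soma, ax)
            return mean, lag

        m0, l0 = pipeline(tr, bouton)
        # additive offset on both channels
        tr_off = VoltageTrace(0.0, DT, tr.V + 7.0)
        b_off = VoltageTrace(0.0, DT, bouton.V + 7.0)
        m1, l1 = pipeline(tr_off, b_off)
        assert m1 == pytest.approx(m0, abs=1e-9)
        assert l1 == pytest.approx(l0, abs=1e-9)
        # common gain: CR and lag unchanged (threshold scaled along)
        tr_g = VoltageTrace(0.0, DT, -70 + 2 * (tr.V + 70))
        b_g = VoltageTrace(0.0, DT, -70 + 2 * (bouton.V + 70))
        ev = detect_epsps(tr_g, threshold_mV=6.0)
        pairs, _ = match_events(ev, b_g, search_window_ms=10.0)
        _, m2, _ = coupling_ratio(pairs)
        assert m2 == pytest.approx(m0, abs=1e-6)


class TestCrossCorrelationLag:
    def test_identical_traces(self):
        tr, _ = train_trace(n_events=6, duration_ms=10_000)
        assert cross_correlation_lag(tr, tr) == 0.0

    def test_constructed_shift(self):
        tr, _ = train_trace(n_events=6, duration_ms=10_000)
        shift = int(round(2.33 / DT))
        v = np.roll(tr.V, shift)
        v[:shift] = -70.0
        bouton = VoltageTrace(0.0, DT, v)
        assert cross_correlation_lag(tr, bouton) == pytest.approx(2.33, abs=DT)

    def test_antisymmetry(self):
        tr, _ = train_trace(n_events=6, duration_ms=10_000)
        shift = int(round(3.0 / DT))
        v = np.roll(tr.V, shift)
        v[:shift] = -70.0
        bouton = VoltageTrace(0.0, DT, v)
        assert cross_correlation_lag(bouton, tr) == pytest.approx(
            -cross_correlation_lag(tr, bouton))

    def test_constant_trace_rejected(self):
        tr, _ = train_trace(n_events=6, duration_ms=10_000)
        flat = VoltageTrace(0.0, DT, np.zeros(len(tr)))
        with pytest.raises(UndefinedCorrelationError):
            cross_correlation_lag(tr, flat)


class TestFitDecay:
    def test_mono_exponential_exact(self):
        t = np.arange(0, 120, DT)
        seg = VoltageTrace(0.0, DT, -70 + 10 * np.exp(-t / 20.4))
        res = fit_decay(seg, n_exp=1)
        assert res["tau1"] == pytest.approx(20.4, rel=1e-3)

    def test_bi_exponential_recovery(self):
        t = np.arange(0, 150, DT)
        y = -70 + 6 * np.exp(-t / 3.0) + 7 * np.exp(-t / 19.9)
        res = fit_decay(VoltageTrace(0.0, DT, y), n_exp=2)
        assert res["tau1"] == pytest.approx(3.0, rel=0.05)
        assert res["tau2"] == pytest.approx(19.9, rel=0.05)
        assert res["tau1"] < res["tau2"]

    def test_degenerate_second_component_flagged(self):
        t = np.arange(0, 120, DT)
        seg = VoltageTrace(0.0, DT, -70 + 10 * np.exp(-t / 20.0))
        res = fit_decay(seg, n_exp=2)
        assert res.flags.get("degenerate_second_component", False)


class TestLengthConstant:
    def test_noiseless_recovery(self):
        d = np.linspace(64.5, 244.0, 25)
        table = DistanceCrTable(d, np.exp(-d / 181.0))
        res = fit_length_constant(table)
        assert res["lambda_um"] == pytest.approx(181.0, rel=1e-3)
        assert res["A"] == pytest.approx(1.0, rel=1e-3)
        res_c = fit_length_constant(table, constrain_A=True)
        assert res_c["lambda_um"] == pytest.approx(181.0, rel=1e-3)

    def test_prefactor_scale_separation(self):
        d = np.linspace(64.5, 244.0, 25)
        half = DistanceCrTable(d, 0.5 * np.exp(-d / 181.0))
        res = fit_length_constant(half)
        assert res["lambda_um"] == pytest.approx(181.0, rel=1e-3)
        assert res["A"] == pytest.approx(0.5, rel=1e-3)

    def test_constant_cr_unidentifiable(self):
        d = np.linspace(64.5, 244.0, 10)
        res = fit_length_constant(DistanceCrTable(d, np.full(10, 0.6)))
        assert res.flags.get("lambda_unidentifiable", False)


class TestCaSpikeMetrics:
    @staticmethod
    def biphasic(width_us=620.0, dt=0.02, amp=10.0, offset=0.0):
        from cavprime.synth import generate_ca_spike_train
        tr, truth = generate_ca_spike_train(width_us=width_us, amplitude=amp,
                                            rate_Hz=20.0, duration_s=0.5,
                                            noise_sd=0.0, seed=0, dt_ms=dt)
        return CurrentTrace(tr.t0, tr.dt, tr.I + offset), truth

    def test_width_by_construction(self):
        tr, truth = self.biphasic(620.0)
        spikes = ca_spike_metrics(tr, threshold=2.0)
        assert len(spikes) == len(truth)
        widths = [s.width_us for s in spikes]
        assert np.median(widths) == pytest.approx(620.0, abs=1.2 * tr.dt * 1000)

    def test_time_axis_scaling(self):
        tr, _ = self.biphasic(620.0 * 0.45)  # 279 us
        spikes = ca_spike_metrics(tr, threshold=2.0, smooth_ms=0.05)
        assert np.median([s.width_us for s in spikes]) == pytest.approx(
            279.0, abs=1.2 * tr.dt * 1000)

    def test_baseline_offset_invariance(self):
        tr0, _ = self.biphasic(620.0)
        tr1, _ = self.biphasic(620.0, offset=-3.0)
        a0 = [s.amplitude for s in ca_spike_metrics(tr0, threshold=2.0)]
        a1 = [s.amplitude for s in ca_spike_metrics(tr1, threshold=2.0)]
        assert a0 == pytest.approx(a1)


def test_dc_coupling_arithmetic():
    assert dc_coupling_prediction(20.0, 0.7) == 14.0
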