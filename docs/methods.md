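# Methods

## The gating model and its assumptions

The Ca_v model treats the channel's four S4 voltage sensors as independent
and identical. A single sensor's steady activation is the fourth root of a
Boltzmann open-probability curve, `P_open(V) = 1/(1+exp(-alpha*(V-V_Cav50)))`,
and the channel conducts only when all four sensors are active, so the
instantaneous open probability is `P_s(act)^4`. The driving force is ohmic,
`I = P_open * (V - E_Ca)`, with the conductance normalized to 1: simulated
currents are in arbitrary units and only ratios and shapes are compared to
data (no GHK rectification, no inactivation gate — the recorded step
currents show little inactivation — and no stochastic single-channel
simulation or Ca²⁺ diffusion/buffering).

Sensor kinetics are first-order with a state-dependent velocity: activation
runs at `k_on * P_s(steady act)` and deactivation at
`k_off * (1 - P_s(steady act))`. At the activation/deactivation tie the
drive term `(P_steady - P_act)` is zero, so the branch choice is immaterial;
the activation branch is used. The ODE is integrated by forward Euler with
`dt = 0.01 ms` (the permitted range is 0.005–0.05 ms), with `P_s(act)`
clipped to [0, 1] after each step to guard against overshoot at coarse
steps. A convergence utility (`convergence_error`) re-integrates any
protocol at a 10× finer step; for every protocol used here the peak-current
discrepancy is below 1%.

Defaults: `V_Cav50 = -17 mV`, `alpha = 0.2 /mV`, `k_on = 0.55 /ms`,
`k_off = 0.65 /ms`, `E_Ca = +60 mV`. These are the values obtained by
fitting the bouton I–V relationship and step-current time course, and all
simulations use them unless a sweep explicitly scales them.

## Stimulus reconstruction

The original experiments applied *recorded* AP and EPSP waveforms; only
their summary parameters are available, so the builders synthesize stylized
versions and calibrate them to those parameters exactly:

* **AP** — a product of a rising and a falling sigmoid. The separation
  between the two sigmoid centers is solved numerically (Brent bracketing)
  so the interval between the maximal rising and falling slopes — the
  quantity a cell-attached electrode reports as spike width — equals the
  specified 780 µs at the simulation step. Rest is −70 mV, peak +40 mV.
  The two shape constants (rise τ 0.15 ms, decay τ 0.40 ms) are free
  choices; they were set on biophysical grounds so the stylized AP resembles
  an immature bouton AP: maximal rise slope ≈ 183 V/s, ≈ 2.7× the maximal
  fall slope, half-width ≈ 1.05 ms, consistent with the broad (780 µs)
  cell-attached widths of the young age group. The augmentation ratio is
  moderately sensitive to these constants (plausible shapes span roughly
  1.22–1.33), which is why the headline ratio carries a reconstruction
  tolerance rather than a printed-precision one.
* **EPSPs** — dual-exponential transients whose rise constant is solved so
  the 10–90% risetime equals the axonal value (5.7 ms; decay τ 20.4 ms).
  The second EPSP superposes linearly on the first's decay and its amplitude
  is solved so both stated *peak potentials* (−58, −53 mV; interpreted as
  absolute potentials since rest is −70 mV) are honored exactly.
* **Composite** — the AP's departure from rest is aligned to 40 ms after the
  first EPSP onset; test and control share the identical AP segment, spliced
  onto the subthreshold envelope by elementwise maximum. An inserted
  "interval" truncates the EPSP tail to rest that many ms before AP onset.
* **Pre-pulse protocols** — piecewise-constant hold → pre-pulse → optional
  gap → test pulse (default +30 mV for 1.5 ms, pre-pulses 20 ms, −90…−40 mV).

Peak amplitudes are measured as |min(I) − baseline| inside an analysis
window starting at the test-pulse/AP onset, with baseline = mean current
over the 5 ms before the window. Whether the original measurements were
baseline-subtracted is not stated; subtraction makes ratios robust to
holding current and is the package's convention throughout.

## Fitting

All fits are bounded trust-region least squares (scipy) with three starting
points, to avoid the Boltzmann fit's flat directions; bounds are
α ∈ (0.01, 1), V_Cav50 ∈ (−60, 20) mV, rates ∈ (0.005, 55) /ms. Failures
return a flagged result rather than raising. The activation-τ fit
`A(1−e^(−t/τ))+B` runs from current onset (3× baseline-noise crossing,
floored at 1% of peak) to 95% of plateau. Autoreceptor isolation scales the
simulated Ca²⁺ current by a least-squares match over the first 5 ms of the
depolarization (the fast Ca_v-dominated window — the residual autoreceptor
component is slow) before subtracting. The I–V fit is unweighted by default
(per-point spreads can be supplied); whether the original fit was weighted
is unknown.

## Event detection and coupling metrics

The threshold detector's published description names no parameters, so the
conventions here are documented choices, not claimed identical to the
original: detection runs on a 0.5 ms boxcar-smoothed trace; peaks must be
separated by the minimum-separation (closer peaks merge); the onset is the
last sample below baseline + 0.2×threshold before the peak; the baseline is
the median of the 10 ms preceding the onset. Risetime is 10–90% of
baseline-to-peak; decays are fitted from the peak over 5× a τ guess.

Matching pairs each somatic event with the bouton-trace maximum inside
[onset, onset + window] using the same local-baseline amplitude convention;
windows whose peak stays below a 1 mV floor count as unmatched. Note that
with the default 10 ms window and the axonal kernel's ~10 ms time-to-peak,
the axonal amplitude is clipped by ~3%, biasing the recovered coupling
ratio from 0.600 to ≈ 0.58; a 20 ms window removes the bias. The per-cell
coupling ratio is the mean of per-event ratios (the trace-average
alternative is not used). The cross-correlogram lag is the argmax of the
full normalized cross-correlation within ±20 ms; on matched-kinetics shifts
it returns the programmed lag exactly, while on cable-filtered pairs it
also reflects the slowed axonal rise.

The length-constant fit `CR(d) = A·e^(−d/λ)` leaves A free by default
(dendro-somatic attenuation precedes the axon, so CR(0) need not be 1);
constraining A = 1 is available. A fit driven to the λ bound (e.g.
distance-independent CR) is flagged unidentifiable.

CA-spike width/amplitude are measured peak to peak: the negative extremum is
threshold-detected on a lightly smoothed (0.1 ms) trace and paired with the
following positive extremum; the metrics are invariant to baseline offsets.

## Synthetic data

The paired-trace generator emulates the example paired recording: Poisson
event times (spontaneous EPSPs; no ISI statistics were reported), somatic
amplitudes Gaussian 13.1 ± 2.0 mV truncated at zero, event rate 29 events /
50 s, additive Gaussian noise SD 0.5 mV at 0.1 ms sampling. The axonal
channel is phenomenological: per-event amplitude × the true coupling ratio
(0.6), onset shifted by 2.33 ms, slower rise (5.7 vs 1.8 ms 10–90%), and a
matched slow decay (20.4 vs 19.9 ms). This reproduces the statistical
structure the analyses assume — attenuation, lag, risetime slowing, shared
slow decay — but it is not a cable solve: passing recovery tests shows the
pipeline measures what the generator encodes, not that a compartmental
model would produce these traces. CA-spike trains use quasi-regular
(current-step-driven) timing with 2% interval jitter and biphasic
double-Gaussian spikes whose extrema separation is the programmed width.
Every generator takes one integer seed and returns its ground truth.

## Problem sizes and numerical choices

The repository's standard runs use: 200 replicates of 25-cell tables for the
length-constant Monte Carlo (noise CV 0.15, distances uniform on 64.5–244
µm), one 50 s paired recording for the coupling-ratio recovery, and 50
replicates for the kinetics recovery (noise 2% of peak). The Euler
integrator touches ~10⁴ samples per protocol at dt = 0.01 ms. Degenerate
inputs are handled as flags, not exceptions: all-zero I–V data, commands
without a repolarizing tail (k_off unidentifiable), distance-independent
coupling tables (λ unidentifiable), and bi-exponential fits that collapse
onto one component.

## Known limitations

* The AP/EPSP waveforms are stylized reconstructions; absolute simulated
  amplitudes are in normalized units and only ratios are meaningful.
* The augmentation ratio inherits uncertainty from the free AP shape
  constants (see above).
* The generator's axonal filtering is phenomenological; no multicompartment
  cable model, vesicle-release model, or autoreceptor-conductance model is
  included (the autoreceptor component is only *isolated*, by subtraction).
* Detector conventions are plausible defaults, not the original tool's.
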