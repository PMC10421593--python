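#!/usr/bin/env python
"""Inverse problems: parameter recovery and autoreceptor-current isolation.

Fits (V_Cav50, alpha) to noisy I-V data and (k_on, k_off) to noisy step
currents generated by the model itself, then demonstrates isolation of a
slow injected (autoreceptor-like) component by amplitude-matched
subtraction.
"""
from pathlib import Path

import numpy as np
import pandas as pd

from cavprime import CavParams, IVDataset, fit_iv, fit_kinetics, \
    isolate_autoreceptor, simulate_current, steady_iv_curve
from cavprime.synth import NoiseSpec, generate_noisy_ica
from cavprime.workflows import canonical_step, kon_recovery_median

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)
params = CavParams()
SEED = 20260921

# I-V fit recovery under 5% multiplicative noise
iv = steady_iv_curve(np.linspace(-60, 50, 16), params)
rows = []
for s in range(100):
    rng = np.random.default_rng(SEED + s)
    noisy = iv[:, 1] * (1 + 0.05 * rng.standard_normal(16))
    res = fit_iv(IVDataset(iv[:, 0], noisy), E_Ca=60.0)
    rows.append((s, res["V_Cav50"], res["alpha"], res.converged))
df = pd.DataFrame(rows, columns=["seed", "V_Cav50", "alpha", "converged"])
df.to_csv(OUT / "iv_fit_recovery.tsv", sep="\t", index=False)
print(f"I-V fit, 5% noise, 100 seeds: median V_Cav50 = "
      f"{df.V_Cav50.median():.2f} mV (truth -17), median alpha = "
      f"{df.alpha.median():.3f} (truth 0.2)")

# kinetics fit recovery at 2%-of-peak noise
med_kon = kon_recovery_median(n_replicates=50, seed=SEED)
print(f"kinetics fit, 2%-of-peak noise, 50 seeds: median k_on = "
      f"{med_kon:.3f} /ms (truth 0.55)")

# autoreceptor isolation: inject a slow transient, recover it by subtraction
stim = canonical_step(params)
clean, _ = simulate_current(stim, params)
recorded, truth = generate_noisy_ica(params, stim, NoiseSpec(seed=SEED),
                                     noise_frac_of_peak=0.01,
                                     slow_transient=(8.0, 40.0))
resid, scale = isolate_autoreceptor(recorded, clean)
pd.DataFrame({"time_ms": resid.t, "residual": resid.I,
              "injected": truth["transient"].I}).to_csv(
    OUT / "autoreceptor_isolation.tsv", sep="\t", index=False)
rms = np.sqrt(np.mean((resid.I - truth["transient"].I) ** 2))
print(f"autoreceptor isolation: fitted scale {scale:.3f}, residual-vs-"
      f"injected RMS error {rms:.3f} (noise SD "
      f"{0.01 * abs(clean.I.min()):.3f})")
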