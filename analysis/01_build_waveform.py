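#!/usr/bin/env python
"""Build the quiet-breathing waveform (0.5 L tidal at 12 breaths/min).

Generates the default template rescaled and amplitude-normalized so each
phase of the interpolated waveform moves exactly the tidal volume, reports
the phase integrals and peaks, and writes the sampled curve to
results/waveform.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import quad

import maskco2 as m

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

pattern = m.build_pattern(target_frequency=12.0, target_tidal_volume=0.5)
v_in = -quad(pattern.flow, 0, pattern.t_ins, epsabs=1e-12, limit=200)[0]
v_ex = quad(pattern.flow, pattern.t_ins, pattern.t_resp, epsabs=1e-12,
            limit=200)[0]
t = np.linspace(0, pattern.t_resp, 5001)
f = pattern.flow(t)
t_peak_exp = t[t >= pattern.t_ins][np.argmax(f[t >= pattern.t_ins])]

print(f"cycle: {pattern.t_resp:.1f} s "
      f"({pattern.t_ins:.1f} s inspiration / {pattern.t_exp:.1f} s expiration)")
print(f"phase volumes: inspiration {v_in:.12f} L, expiration {v_ex:.12f} L")
print(f"peak inspiratory flow: {-f.min():.3f} L/s at t = {t[np.argmin(f)]:.2f} s")
print(f"peak expiratory flow:  {f.max():.3f} L/s at t = {t_peak_exp:.2f} s "
      "(early in expiration, as in measured quiet breathing)")

pd.DataFrame(pattern.sample(1001), columns=["t_s", "flow_L_per_s"]).to_csv(
    OUT / "waveform.csv", index=False, float_format="%.10g")
print(f"wrote {OUT / 'waveform.csv'}")
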