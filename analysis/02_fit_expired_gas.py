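#!/usr/bin/env python
"""Fit the expired-CO2 transition times to the physiology card.

The anatomic dead space (0.15 L, expired first at ambient CO2) pins t_pd;
the CO2 volume of one expiration (0.018 L) pins the mixing-ramp length
t_mix.  Writes the fitted profile sampled over expiration to
results/expired_gas.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import maskco2 as m
from maskco2.expired_gas import constraint_residuals

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

pattern = m.build_pattern()
profile = m.fit_profile(pattern, 0.0004, 0.053, 0.15, 0.018)
r_ads, r_co2 = constraint_residuals(pattern, profile)

print(f"t_pd  = {profile.t_pd:.6f} s  (dead-space washout ends; "
      f"residual {r_ads:.2e} L)")
print(f"t_mix = {profile.t_mix:.6e} s (ramp to alveolar air; "
      f"residual {r_co2:.2e} L)")
print("sanity: phi_alv*(V_tid - V_ads) = "
      f"{0.053 * 0.35:.5f} L > V_CO2 = 0.018 L, so a positive ramp exists")

t = np.linspace(pattern.t_ins, pattern.t_resp, 2001)
pd.DataFrame({
    "t_s": t,
    "flow_L_per_s": pattern.flow(t),
    "phi_exp": m.phi_exp(profile, t),
    "cum_expired_L": [pattern.expired_volume(x) for x in t],
}).to_csv(OUT / "expired_gas.csv", index=False, float_format="%.10g")
print(f"wrote {OUT / 'expired_gas.csv'}")
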