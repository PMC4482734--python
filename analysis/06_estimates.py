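#!/usr/bin/env python
"""Closed-form estimates: inspired-CO2 dilution and exit-speed scaling.

These need no ODE solve; they bound what the simulations should return and
quantify why a passive mask promotes rebreathing (slow diffuse outflow)
while the blower restores a jet.  Writes results/estimates.csv.
"""

from pathlib import Path

import pandas as pd

import maskco2 as m

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

rows = []
for label, phi_end in (("standard", 0.052), ("avs", 0.004)):
    est = m.inspired_fraction_estimate(phi_end, 0.1, 0.5, 0.0004)
    rows.append({"case": label, "phi_end_pct": 100 * phi_end,
                 "inspired_exact_pct": 100 * est.exact,
                 "inspired_simplified_pct": 100 * est.simplified})
    print(f"{label:>8}: end-expiration {100 * phi_end:.1f} % -> inspired "
          f"~{100 * est.simplified:.2f} % (exact {100 * est.exact:.3f} %)")

filter_speed = m.mean_exit_speed(20.0, 100e-4)
fan = m.FanModel()
op = m.avs_operating_point(fan, m.FilterModel(
    m.fit_permeability(10.0, 85.0, 100e-4, 1.25e-3), 132e-4, 1.25e-3), 0.0)
jet_speed = m.mean_exit_speed(op.fan_flow * 60000.0, fan.outlet_area)
print(f"passive filter outflow ~{filter_speed.speed:.3f} m/s "
      f"(decade 1e{filter_speed.decade}) — expired air lingers near the face")
print(f"blower jet ~{jet_speed.speed:.2f} m/s (decade 1e{jet_speed.decade}) "
      "— comparable to a natural expiratory jet")

rows.append({"case": "filter_exit_speed_ms", "phi_end_pct": float("nan"),
             "inspired_exact_pct": filter_speed.speed,
             "inspired_simplified_pct": filter_speed.decade})
pd.DataFrame(rows).to_csv(OUT / "estimates.csv", index=False,
                          float_format="%.10g")
print(f"wrote {OUT / 'estimates.csv'}")
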