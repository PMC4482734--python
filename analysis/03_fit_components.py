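#!/usr/bin/env python
"""Fit the filter permeability and locate the fan-filter operating point.

Inverts the Darcy law against the manufacturer card (10 mmAq at 85 L/min
over 100 cm^2, 1.25 mm sheet), verifies the round trip, evaluates the peak
breathing pressure drop through the 137.5 cm^2 mask filter, and solves the
quiescent fan-filter operating point for the AVS (132 cm^2 filter).
Writes results/components.csv.
"""

from pathlib import Path

import pandas as pd

import maskco2 as m

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

kappa = m.fit_permeability(10.0, 85.0, 100e-4, 1.25e-3, 1.9e-5)
spec = m.FilterModel(kappa, 100e-4, 1.25e-3, 1.9e-5, 0.88)
rt = m.filter_pressure_drop(spec, 85.0 / 60000.0) / m.MMAQ_PA
print(f"kappa = {kappa:.4e} m^2 (round trip {rt:.6f} mmAq)")

pattern = m.build_pattern()
std = spec.with_area(137.5e-4)
peak_dp = m.filter_pressure_drop(std, pattern.peak_flow() / 1000.0)
print(f"peak breathing pressure drop through the standard filter: "
      f"{peak_dp:.2f} Pa (small against 1 atm, as the flow model assumes)")

fan = m.FanModel()
avs = spec.with_area(132e-4)
op = m.avs_operating_point(fan, avs, 0.0)
jet = m.mean_exit_speed(op.fan_flow * 60000.0, fan.outlet_area)
print(f"quiescent operating point: fan flow {op.fan_flow * 60000:.2f} L/min "
      f"at {op.fan_pressure:.2f} Pa static pressure")
print(f"blower jet speed {jet.speed:.2f} m/s (~1e{jet.decade} m/s), vs "
      f"~1e-2 m/s seeping through a passive filter")

pd.DataFrame([{
    "kappa_m2": kappa, "round_trip_mmaq": rt, "peak_filter_dp_pa": peak_dp,
    "rest_fan_flow_m3s": op.fan_flow, "rest_fan_pressure_pa": op.fan_pressure,
    "rest_jet_speed_ms": jet.speed,
}]).to_csv(OUT / "components.csv", index=False, float_format="%.10g")
print(f"wrote {OUT / 'components.csv'}")
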