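#!/usr/bin/env python
"""Steady-periodic CO2 with the active venting system (AVS).

Calibrates the jet-capture fraction so the steady-periodic end-of-expiration
CO2 matches the 0.4% level of the spatially resolved reference, then reports
the cycle average and inspired average.  Writes cycle and summary CSVs under
results/.
"""

import logging
from pathlib import Path

from maskco2.config import RunConfig, run_pipeline

logging.basicConfig(level=logging.INFO, format="%(levelname)s: %(message)s")
OUT = Path(__file__).resolve().parent.parent / "results"

summary = run_pipeline(RunConfig(mode="avs"), out_dir=OUT)

print()
print("AVS-equipped mask, steady periodic:")
print(f"  calibrated capture fraction eta = {summary['eta']:.3f}")
print(f"  phi_0 (cycle start)    {100 * summary['phi0']:.2f} %")
print(f"  end of expiration      {100 * summary['end_expiration']:.2f} %")
print(f"  cycle time average     {100 * summary['time_average']:.2f} %")
print(f"  inspired average       {100 * summary['inspired_average']:.3f} %  "
      f"(dilution estimate {100 * summary['inspired_estimate_simplified']:.3f} %)")
print("the blower keeps the inspired CO2 near ambient levels, roughly a "
      "ten-fold reduction over the passive mask")
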