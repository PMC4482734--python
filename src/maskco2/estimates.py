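"""Closed-form back-of-envelope estimates.

Two quick checks that need no ODE solve:

* the inspired-CO2 dilution estimate — the wearer first re-inhales the
  dead-space volume V_ds at its end-expiratory fraction, then ambient air
  for the rest of the tidal volume:

      phi_ins = (phi_end * V_ds + phi_amb * (V_tid - V_ds)) / V_tid
              ~ phi_end * V_ds / V_tid        (ambient term dropped)

* the mean exit speed of expired air through an outflow area, from bulk
  mass conservation:  |u.n| ~ Q / A, reported together with its order of
  magnitude (nearest power of ten).
"""

from __future__ import annotations

import math
from typing import NamedTuple

__all__ = ["InspiredEstimate", "ExitSpeed", "inspired_fraction_estimate",
           "mean_exit_speed"]


class InspiredEstimate(NamedTuple):
    exact: float  # (phi_end*V_ds + phi_amb*(V_tid - V_ds)) / V_tid
    simplified: float  # phi_end * V_ds / V_tid


class ExitSpeed(NamedTuple):
    speed: float  # m/s
    decade: int  # exponent of the nearest power of ten


def inspired_fraction_estimate(
    phi_end: float, v_ds: float, v_tid: float, phi_amb: float
) -> InspiredEstimate:
    """Dead-space dilution estimate of the inspired CO2 volume fraction.

    All fractions dimensionless, volumes in liter.  Returns both the exact
    two-term form and the simplified form that drops the ambient
    contribution (roughly a hundred times smaller than the dead-space term
    for a passive mask).
    """
    if min(phi_end, v_ds, v_tid) < 0 or phi_amb < 0:
        raise ValueError("all inputs must be non-negative")
    if v_ds >= v_tid:
        raise ValueError("dead-space volume must be smaller than the tidal volume")
    exact = (phi_end * v_ds + phi_amb * (v_tid - v_ds)) / v_tid
    return InspiredEstimate(exact=exact, simplified=phi_end * v_ds / v_tid)


def _nearest_decade(x: float) -> int:
    """Exponent d minimizing |x - 10**d|; ties go to the larger decade."""
    lo = math.floor(math.log10(x))
    hi = lo + 1
    return hi if abs(x - 10.0 ** hi) <= abs(x - 10.0 ** lo) else lo


def mean_exit_speed(flow_lpm: float, area: float) -> ExitSpeed:
    """Bulk exit speed of air through an outflow area.

    flow in liter/min, area in m^2; returns the speed in m/s and the
    exponent of its nearest power of ten (nearest in linear distance, so
    0.033 m/s reports decade -2 and 0.57 m/s reports decade 0).  Zero flow
    returns speed 0 with decade 0 by convention.
    """
    if flow_lpm < 0 or area <= 0:
        raise ValueError("flow must be >= 0 and area > 0")
    speed = flow_lpm / 1000.0 / 60.0 / area
    if speed == 0.0:
        return ExitSpeed(0.0, 0)
    return ExitSpeed(speed, _nearest_decade(speed))
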