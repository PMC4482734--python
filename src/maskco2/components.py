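"""Filter and blower models and the lumped fan-filter operating point.

The filter is a Darcy porous sheet: pressure drop linear in flow with
conductance G = kappa * A / (mu * L_f).  The permeability kappa is fitted by
inverting the Darcy law against the manufacturer specification (pressure drop
at a reference flow and face area).  The blower is a clamped linear fan
characteristic, static pressure p_fan = max(a - b * Q_fan, 0).

The operating point couples the two through a quasi-steady lumped closure:
the mask interior carries one uniform gauge pressure p_m = -p_fan (the fan
sucks the dead space below ambient), the filter admits ambient air at rate
G * p_fan, and mass balance closes the fan flow:

    Q_fan = Q_resp + G * p_fan,   p_fan = max(a - b * Q_fan, 0)

which has the closed-form unclamped solution Q_fan = (Q_resp + G a)/(1 + G b).
Two degenerate branches are handled: the fan curve clamping to zero pressure
during violent expiration, and the one-way valve shutting (fan flow pinned at
zero, the filter carrying the full respiratory flow) when inspiration
overpowers the fan.  With the default fan constants neither branch is reached
during quiet breathing.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "MMAQ_PA", "FilterModel", "FanModel", "OperatingPoint",
    "fit_permeability", "filter_pressure_drop", "fan_pressure",
    "avs_operating_point",
]

#: pascals per millimetre of water column (standard water at 4 degC)
MMAQ_PA = 9.80665


@dataclass(frozen=True)
class FilterModel:
    """Darcy-law porous filter."""

    kappa: float  # permeability, m^2
    area: float  # face area, m^2
    thickness: float  # sheet thickness, m
    mu: float = 1.9e-5  # air dynamic viscosity, Pa s
    porosity: float = 0.88  # dimensionless (carried for reporting)

    def __post_init__(self):
        for name in ("kappa", "area", "thickness", "mu"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.porosity <= 1.0:
            raise ValueError("porosity must lie in (0, 1]")

    @property
    def conductance(self) -> float:
        """G = kappa * A / (mu * L_f), m^3 s^-1 Pa^-1."""
        return self.kappa * self.area / (self.mu * self.thickness)

    def with_area(self, area: float) -> "FilterModel":
        """Same filter medium cut to a different face area (G scales with A)."""
        return FilterModel(self.kappa, area, self.thickness, self.mu, self.porosity)


@dataclass(frozen=True)
class FanModel:
    """Clamped linear fan characteristic p_fan = max(a - b*Q, 0)."""

    a: float = 67.1  # zero-flow static pressure, Pa
    b: float = 1.6216e5  # slope, Pa s m^-3
    outlet_area: float = 5.5e-4  # m^2

    def __post_init__(self):
        if self.a < 0 or self.b <= 0 or self.outlet_area <= 0:
            raise ValueError("need a >= 0, b > 0, outlet_area > 0")

    @property
    def free_delivery(self) -> float:
        """Flow at which the static pressure reaches zero, a/b (m^3/s)."""
        return self.a / self.b


@dataclass(frozen=True)
class OperatingPoint:
    """Quasi-steady fan-filter-respiration balance at one instant."""

    fan_flow: float  # m^3/s, out of the mask through the blower (>= 0)
    fan_pressure: float  # Pa, static pressure of the fan curve
    filter_inflow: float  # m^3/s, ambient air into the mask through the filter
    mask_gauge: float  # Pa, dead-space pressure relative to ambient


def fit_permeability(
    dp_mmaq: float,
    flow_lpm: float,
    area: float,
    thickness: float,
    mu: float = 1.9e-5,
) -> float:
    """Invert the Darcy law against a filter spec sheet.

    kappa = mu * L_f * (Q/A) / dp, with the spec pressure drop in mmAq and
    the spec flow in liter/min.  Round trip: a filter built from the fitted
    kappa reproduces dp_mmaq exactly at the spec flow and area.
    """
    if min(dp_mmaq, flow_lpm, area, thickness, mu) <= 0:
        raise ValueError("all filter-spec arguments must be positive")
    dp_pa = dp_mmaq * MMAQ_PA
    q = flow_lpm / 1000.0 / 60.0  # m^3/s
    return mu * thickness * (q / area) / dp_pa


def filter_pressure_drop(filt: FilterModel, flow: float) -> float:
    """Darcy pressure drop (Pa) at a signed volumetric flow (m^3/s)."""
    return flow / filt.conductance


def fan_pressure(fan: FanModel, flow: float) -> float:
    """Static fan pressure (Pa) on the clamped linear characteristic."""
    if flow < 0:
        raise ValueError("fan flow must be non-negative")
    return max(fan.a - fan.b * flow, 0.0)


def avs_operating_point(
    fan: FanModel, filt: FilterModel, respiratory_flow: float
) -> OperatingPoint:
    """Solve the instantaneous fan-filter balance for a signed nostril flow.

    respiratory_flow is in m^3/s, positive during expiration.  Branches:

    * unclamped: Q_fan = (Q_resp + G a)/(1 + G b), valid while the implied
      static pressure is positive and the fan flow non-negative;
    * pressure clamp (Q_fan would exceed free delivery): p_fan = 0, the mask
      sits at ambient pressure, the filter carries nothing and the fan
      exhausts the full expiratory flow;
    * valve shut (inspiration overpowering the fan, Q_resp < -G a): the
      one-way valve blocks back-flow, the fan is pinned at zero flow and the
      filter carries the whole respiratory flow like a passive mask.

    Mass balance filter_inflow = fan_flow - respiratory_flow holds exactly in
    every branch.
    """
    g = filt.conductance
    q_fan = (respiratory_flow + g * fan.a) / (1.0 + g * fan.b)
    if q_fan < 0.0:
        # valve shut: passive-mask behaviour
        return OperatingPoint(
            fan_flow=0.0,
            fan_pressure=fan.a,
            filter_inflow=-respiratory_flow,
            mask_gauge=respiratory_flow / g,
        )
    p_fan = fan.a - fan.b * q_fan
    if p_fan < 0.0:
        # fan past free delivery: zero static pressure, valve wide open
        q_fan = max(respiratory_flow, 0.0)
        return OperatingPoint(
            fan_flow=q_fan, fan_pressure=0.0,
            filter_inflow=q_fan - respiratory_flow, mask_gauge=0.0,
        )
    return OperatingPoint(
        fan_flow=q_fan,
        fan_pressure=p_fan,
        filter_inflow=g * p_fan,
        mask_gauge=-p_fan,
    )
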