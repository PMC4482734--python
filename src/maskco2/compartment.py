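"""Dead-space CO2 balance: compartment ODE, steady-periodic solver, summaries.

The mask dead space (0.1 L between face and filter) is treated as a single
well-mixed compartment with CO2 volume fraction phi(t).  Quasi-steady flows
move air through it:

* standard mask, expiration: the nostrils inject expired air at phi_exp(t)
  and an equal flow leaves through the filter at the mixed fraction phi;
* standard mask, inspiration: ambient air enters through the filter at
  phi_amb and the nostrils withdraw mixed air at phi;
* with the active venting system (AVS): the instantaneous fan-filter
  operating point sets the fan and filter flows at every t.  During
  expiration a fraction eta of the expired stream (the "jet-capture
  fraction") bypasses the mixed zone and is sucked straight out by the
  blower — the lumped surrogate for the direct capture of the expired jet
  that a spatially resolved model would show.  The rest mixes as usual.

The balance is the linear ODE

    V_ds dphi/dt = sum_i Q_in,i * phi_in,i  -  (sum_j Q_out,j) * phi

integrated segment-by-segment (segment edges at the phase boundaries and at
the expired-profile transition times, so the integrator never steps over the
~0.07 s mixing ramp).  Because the ODE is linear, the cycle map
phi_start -> phi_end is affine and the steady-periodic state is reached in a
handful of fixed-point iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad, solve_ivp
from scipy.optimize import brentq

from .components import FanModel, FilterModel, avs_operating_point
from .errors import CalibrationError, ConvergenceError, ModelLimitError
from .expired_gas import ExpiredGasProfile, phi_exp
from .respiration import BreathingPattern

__all__ = [
    "MaskConfig", "CycleSolution", "simulate_cycle", "solve_steady_periodic",
    "time_average", "end_expiration_value", "inspired_average",
    "calibrate_capture_fraction", "cycle_co2_balance",
]

_L_PER_M3 = 1000.0


@dataclass(frozen=True)
class MaskConfig:
    """Geometry and closure parameters of one mask variant."""

    v_ds: float  # dead-space volume, liter
    filter: FilterModel
    fan: FanModel | None = None  # None for the standard (passive) mask
    eta: float = 0.0  # jet-capture fraction, dimensionless
    phi_amb: float = 0.0004  # ambient CO2 volume fraction

    def __post_init__(self):
        if self.v_ds <= 0:
            raise ValueError("dead-space volume must be positive")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must lie in [0, 1]")
        if self.fan is None and self.eta != 0.0:
            raise ValueError("eta must be 0 for a mask without a fan")
        if not 0.0 <= self.phi_amb < 1.0:
            raise ValueError("phi_amb must be a fraction in [0, 1)")

    def with_eta(self, eta: float) -> "MaskConfig":
        return MaskConfig(self.v_ds, self.filter, self.fan, eta, self.phi_amb)


@dataclass
class CycleSolution:
    """Time-resolved state of one breathing cycle."""

    t: np.ndarray  # s, grid over one cycle [0, t_resp]
    phi: np.ndarray  # dead-space CO2 volume fraction on the grid
    fan_flow: np.ndarray  # m^3/s out through the blower (0 for standard)
    filter_flow: np.ndarray  # m^3/s into the mask through the filter
    mask_gauge: np.ndarray  # Pa, dead-space pressure relative to ambient
    phi_start: float
    phi_end: float
    t_resp: float
    t_ins: float
    cycles: int = 0  # fixed-point iterations used (0 for a single pass)
    _interpolants: list = field(default_factory=list, repr=False)

    def phi_at(self, t: float) -> float:
        """phi from the integrator's dense output (t within [0, t_resp])."""
        for lo, hi, sol in self._interpolants:
            if lo - 1e-12 <= t <= hi + 1e-12:
                return float(sol(np.clip(t, lo, hi)))
        raise ValueError(f"t={t} outside the solved cycle")


def _rates(config: MaskConfig, pattern: BreathingPattern,
           profile: ExpiredGasProfile, t: float):
    """(mixed-zone inflow L/s at phi_exp, filter inflow L/s at phi_amb,
    fan flow m^3/s, mask gauge Pa) at time t."""
    q = pattern.flow(t)  # L/s, expiration positive
    if config.fan is None:
        if q >= 0.0:
            return (q, 0.0, 0.0, q / _L_PER_M3 / config.filter.conductance)
        return (0.0, -q, 0.0, q / _L_PER_M3 / config.filter.conductance)
    op = avs_operating_point(config.fan, config.filter, q / _L_PER_M3)
    q_exp_mixed = (1.0 - config.eta) * max(q, 0.0)
    q_filt = op.filter_inflow * _L_PER_M3
    if q_filt < -1e-12:
        raise ModelLimitError("negative filter inflow in the AVS closure")
    return (q_exp_mixed, max(q_filt, 0.0), op.fan_flow, op.mask_gauge)


def simulate_cycle(
    config: MaskConfig,
    pattern: BreathingPattern,
    profile: ExpiredGasProfile,
    phi_start: float,
    *,
    rtol: float = 1e-10,
    atol: float = 1e-13,
    max_step: float = 0.01,
    grid_step: float = 0.005,
) -> CycleSolution:
    """Integrate the dead-space CO2 balance over one breathing cycle.

    The cycle is split at inspiration end and at the expired-profile
    transition times; each segment is integrated with a dense-output
    adaptive RK method (max step 0.01 s so the mixing ramp is resolved).
    """
    if not 0.0 <= phi_start <= 1.0:
        raise ValueError("phi_start must be a fraction in [0, 1]")

    def rhs(t, y):
        q_exp, q_filt, _, _ = _rates(config, pattern, profile, t)
        inflow_co2 = q_exp * phi_exp(profile, t) + q_filt * config.phi_amb
        outflow = q_exp + q_filt
        return [(inflow_co2 - outflow * y[0]) / config.v_ds]

    edges = sorted({0.0, pattern.t_ins, pattern.t_resp} | {
        p for p in (profile.t_pd, profile.t_pd + profile.t_mix)
        if 0.0 < p < pattern.t_resp
    })

    ts, phis, interps = [], [], []
    y0 = phi_start
    for lo, hi in zip(edges[:-1], edges[1:]):
        sol = solve_ivp(
            rhs, (lo, hi), [y0], method="DOP853", dense_output=True,
            rtol=rtol, atol=atol, max_step=max_step,
        )
        if not sol.success:  # pragma: no cover - smooth linear ODE
            raise ConvergenceError(f"ODE integration failed on [{lo}, {hi}]: {sol.message}")
        n = max(int(np.ceil((hi - lo) / grid_step)), 4)
        seg_t = np.linspace(lo, hi, n + 1)
        seg_phi = sol.sol(seg_t)[0]
        if ts:
            seg_t, seg_phi = seg_t[1:], seg_phi[1:]
        ts.append(seg_t)
        phis.append(seg_phi)
        interps.append((lo, hi, lambda t, s=sol: s.sol(t)[0]))
        y0 = float(sol.y[0, -1])

    t = np.concatenate(ts)
    phi = np.concatenate(phis)
    fan = np.empty_like(t)
    filt = np.empty_like(t)
    gauge = np.empty_like(t)
    for i, ti in enumerate(t):
        q_exp, q_filt, q_fan, p_m = _rates(config, pattern, profile, ti)
        fan[i] = q_fan
        # filter flow positive into the mask; the passive mask vents the
        # full respiratory flow through the filter
        if config.fan is None:
            filt[i] = -pattern.flow(ti) / _L_PER_M3
        else:
            filt[i] = q_filt / _L_PER_M3
        gauge[i] = p_m
    return CycleSolution(
        t=t, phi=phi, fan_flow=fan, filter_flow=filt, mask_gauge=gauge,
        phi_start=phi_start, phi_end=float(phi[-1]),
        t_resp=pattern.t_resp, t_ins=pattern.t_ins,
        _interpolants=interps,
    )


def solve_steady_periodic(
    config: MaskConfig,
    pattern: BreathingPattern,
    profile: ExpiredGasProfile,
    phi_init: float | None = None,
    tol: float = 1e-8,
    max_cycles: int = 200,
    **sim_kwargs,
) -> CycleSolution:
    """Iterate cycles until the start-of-cycle fraction is a fixed point.

    Each cycle's end value seeds the next start; the affine cycle map
    contracts geometrically, so convergence to |phi_start - phi_end| < tol
    typically takes a few cycles.  Returns the converged cycle with its
    phi_0 in ``phi_start`` and the iteration count in ``cycles``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    phi0 = config.phi_amb if phi_init is None else phi_init
    for k in range(1, max_cycles + 1):
        sol = simulate_cycle(config, pattern, profile, phi0, **sim_kwargs)
        if abs(sol.phi_end - sol.phi_start) < tol:
            sol.cycles = k
            return sol
        phi0 = sol.phi_end
    raise ConvergenceError(
        f"steady-periodic iteration did not converge in {max_cycles} cycles "
        f"(last residual {abs(sol.phi_end - sol.phi_start):.3e})"
    )


def time_average(solution: CycleSolution) -> float:
    """Cycle-mean CO2 fraction: (1/t_resp) * int phi dt (trapezoidal)."""
    return float(np.trapezoid(solution.phi, solution.t) / solution.t_resp)


def end_expiration_value(solution: CycleSolution) -> float:
    """phi at the end of expiration (t = t_resp)."""
    return float(solution.phi[-1])


def inspired_average(solution: CycleSolution, pattern: BreathingPattern) -> float:
    """Flow-weighted mean CO2 fraction of the inspired air.

    int |flow| * phi dt / int |flow| dt over the inspiratory phase.
    """
    mask = solution.t <= solution.t_ins + 1e-12
    t = solution.t[mask]
    w = np.abs(pattern.flow(t))
    num = np.trapezoid(w * solution.phi[mask], t)
    den = np.trapezoid(w, t)
    return float(num / den)


def calibrate_capture_fraction(
    config: MaskConfig,
    pattern: BreathingPattern,
    profile: ExpiredGasProfile,
    target_end_value: float,
    tol: float = 1e-6,
    **solve_kwargs,
) -> float:
    """Find the jet-capture fraction eta reproducing a target end-of-expiration phi.

    The steady-periodic end value decreases monotonically in eta, so the root
    is bracketed on [0, 1] and solved by Brent's method; the returned eta
    reproduces the target within ``tol`` (fraction, default 1e-6 = 1e-4
    percentage points).
    """
    if config.fan is None:
        raise CalibrationError("capture-fraction calibration requires a fan")

    def end_at(eta: float) -> float:
        sol = solve_steady_periodic(config.with_eta(eta), pattern, profile,
                                    **solve_kwargs)
        return end_expiration_value(sol)

    hi_val = end_at(0.0)
    lo_val = end_at(1.0)
    if not lo_val - tol <= target_end_value <= hi_val + tol:
        raise CalibrationError(
            f"target end value {target_end_value:.6g} outside the achievable "
            f"bracket [{lo_val:.6g} (eta=1), {hi_val:.6g} (eta=0)]"
        )
    if target_end_value >= hi_val:
        return 0.0
    if target_end_value <= lo_val:
        return 1.0
    eta = brentq(lambda e: end_at(e) - target_end_value, 0.0, 1.0, xtol=1e-8)
    return float(eta)


def cycle_co2_balance(
    config: MaskConfig,
    pattern: BreathingPattern,
    profile: ExpiredGasProfile,
    solution: CycleSolution,
) -> tuple[float, float, float]:
    """CO2 bookkeeping over one cycle via adaptive quadrature.

    Returns (inflow, outflow, relative imbalance): total CO2 volume entering
    the mixed zone (expired stream at phi_exp + filter stream at phi_amb),
    total leaving at the mixed fraction phi, and their difference relative to
    the gross throughput.  At steady periodicity the imbalance is bounded by
    the periodicity tolerance times V_ds.
    """

    def f_in(t):
        q_exp, q_filt, _, _ = _rates(config, pattern, profile, t)
        return q_exp * phi_exp(profile, t) + q_filt * config.phi_amb

    def f_out(t):
        q_exp, q_filt, _, _ = _rates(config, pattern, profile, t)
        return (q_exp + q_filt) * solution.phi_at(t)

    edges = sorted({0.0, pattern.t_ins, pattern.t_resp} | {
        p for p in (profile.t_pd, profile.t_pd + profile.t_mix)
        if 0.0 < p < pattern.t_resp
    })
    vin = vout = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        vin += quad(f_in, lo, hi, epsabs=1e-11, epsrel=1e-11, limit=300)[0]
        vout += quad(f_out, lo, hi, epsabs=1e-11, epsrel=1e-11, limit=300)[0]
    gross = max(vin, vout)
    return vin, vout, (vin - vout) / gross if gross > 0 else 0.0
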