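"""Expired-air CO2 volume-fraction profile and its constrained fit.

During expiration the air leaving the nostrils is not at a uniform CO2
fraction: the anatomic dead space of the airways empties first at essentially
ambient CO2, then a short mixing ramp blends into alveolar air, which forms
the end-tidal plateau.  The profile is the three-segment piecewise function

    phi_exp(t) = phi_amb                      for M(t) <  t_pd
                 linear ramp                  for t_pd <= M(t) < t_pd + t_mix
                 phi_alv                      for M(t) >= t_pd + t_mix

with M(t) = mod(t, t_resp).  The two transition times are not free: t_pd is
pinned by requiring the expired volume up to t_pd to equal the anatomic
dead-space volume V_ads, and t_mix by requiring the CO2 volume carried by one
full expiration to equal V_CO2.  Both are solved by bracketed root finding on
the (monotone) constraint integrals; the cumulative-volume integral uses the
exact antiderivative of the expiratory spline.

Rebreathed CO2 is deliberately *not* fed back into phi_exp: the first expired
air is at phi_amb even though the wearer inspires elevated CO2 from the mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .errors import ParameterInconsistencyError
from .respiration import BreathingPattern

__all__ = ["ExpiredGasProfile", "cycle_modulus", "phi_exp", "fit_transition_times",
           "fit_profile"]

#: absolute tolerance of the constraint integrals, liter
_VOL_TOL = 1e-9
#: bisection tolerance on the fitted times, s
_TIME_TOL = 1e-9


def cycle_modulus(t, t_resp: float):
    """Time folded into the base cycle: mod(t, t_resp), in [0, t_resp)."""
    if t_resp <= 0:
        raise ValueError("t_resp must be positive")
    r = np.mod(t, t_resp)
    # np.mod(-eps, T) can round to exactly T; fold it back to 0
    return np.where(r >= t_resp, 0.0, r) if np.ndim(r) else (
        0.0 if r >= t_resp else float(r))


@dataclass(frozen=True)
class ExpiredGasProfile:
    """Piecewise expired-CO2 volume fraction with fitted transition times."""

    phi_amb: float  # ambient CO2 volume fraction, dimensionless
    phi_alv: float  # alveolar CO2 volume fraction, dimensionless
    t_pd: float  # end of anatomic dead-space washout, s from cycle start
    t_mix: float  # mixing-ramp duration, s
    t_resp: float  # cycle period, s
    t_ins: float  # end of inspiration, s
    v_ads: float  # anatomic dead-space volume, liter
    v_co2: float  # CO2 volume per expiration, liter

    def __post_init__(self):
        if not 0.0 <= self.phi_amb < self.phi_alv <= 1.0:
            raise ParameterInconsistencyError("need 0 <= phi_amb < phi_alv <= 1")
        if self.t_pd < self.t_ins:
            raise ParameterInconsistencyError("t_pd must lie inside expiration")
        if self.t_pd + self.t_mix > self.t_resp + 1e-12:
            raise ParameterInconsistencyError("ramp must end within the cycle")
        if self.t_mix < 0:
            raise ParameterInconsistencyError("t_mix must be non-negative")

    def __call__(self, t):
        return phi_exp(self, t)


def phi_exp(profile: ExpiredGasProfile, t):
    """Expired CO2 volume fraction at time t (periodic; any real t).

    Ramp interval is half-open, [t_pd, t_pd + t_mix).  The value is defined
    for all t but only consumed while the expiratory flow is positive.
    """
    ramp_end = profile.t_pd + profile.t_mix
    if np.ndim(t) == 0:
        m = float(t) % profile.t_resp
        if m < profile.t_pd:
            return profile.phi_amb
        if m < ramp_end:
            return profile.phi_amb + (profile.phi_alv - profile.phi_amb) * (
                (m - profile.t_pd) / profile.t_mix)
        return profile.phi_alv
    m = cycle_modulus(np.asarray(t, dtype=float), profile.t_resp)
    if profile.t_mix > 0:
        ramp = profile.phi_amb + (profile.phi_alv - profile.phi_amb) * (
            (m - profile.t_pd) / profile.t_mix
        )
    else:
        ramp = np.full_like(m, profile.phi_alv)
    out = np.where(
        m < profile.t_pd,
        profile.phi_amb,
        np.where(m < ramp_end, ramp, profile.phi_alv),
    )
    return out if out.ndim else float(out)


def _co2_volume(pattern: BreathingPattern, profile: ExpiredGasProfile) -> float:
    """CO2 volume (liter) carried by one expiration: int V_exp(t) phi_exp(t) dt."""
    pts = sorted(
        p for p in (profile.t_pd, profile.t_pd + profile.t_mix)
        if pattern.t_ins < p < pattern.t_resp
    )
    val, _ = quad(
        lambda t: pattern.flow(t) * phi_exp(profile, t),
        pattern.t_ins, pattern.t_resp,
        points=pts, epsabs=_VOL_TOL, epsrel=1e-12, limit=200,
    )
    return val


def fit_transition_times(
    pattern: BreathingPattern,
    phi_amb: float,
    phi_alv: float,
    v_ads: float,
    v_co2: float,
) -> tuple[float, float]:
    """Fit (t_pd, t_mix) so the profile carries the prescribed volumes.

    t_pd solves  int_{t_ins}^{t_pd} flow dt = v_ads  (cumulative expired
    volume is strictly increasing wherever flow > 0); t_mix then solves
    int_{t_ins}^{t_resp} flow * phi_exp dt = v_co2  (the integral is
    continuous and strictly decreasing in t_mix).  Residuals < 1e-6 liter.
    """
    v_tid = pattern.v_tid
    if not 0.0 <= phi_amb < phi_alv <= 1.0:
        raise ParameterInconsistencyError("need 0 <= phi_amb < phi_alv <= 1")
    if v_ads < 0 or v_ads >= v_tid:
        raise ParameterInconsistencyError(
            f"anatomic dead space v_ads={v_ads} must lie in [0, tidal volume {v_tid})"
        )
    ceiling = phi_amb * v_ads + phi_alv * (v_tid - v_ads)
    if v_co2 >= ceiling:
        raise ParameterInconsistencyError(
            f"v_co2={v_co2} liter is not achievable: even a zero-length mixing "
            f"ramp carries only {ceiling:.6g} liter of CO2 "
            "(requires v_co2 < phi_alv*(v_tid - v_ads) + phi_amb*v_ads)"
        )

    # --- t_pd: root of cumulative expired volume minus v_ads -------------
    if v_ads == 0.0:
        t_pd = pattern.t_ins
    else:
        f = lambda t: pattern.expired_volume(t) - v_ads
        lo, hi = pattern.t_ins, pattern.t_resp
        if f(hi) < 0:  # cannot happen when v_ads < v_tid, kept defensive
            raise ParameterInconsistencyError("expired volume never reaches v_ads")
        t_pd = brentq(f, lo, hi, xtol=_TIME_TOL)

    # --- t_mix: root of the CO2-volume constraint ------------------------
    span = pattern.t_resp - t_pd

    def g(t_mix: float) -> float:
        prof = ExpiredGasProfile(
            phi_amb=phi_amb, phi_alv=phi_alv, t_pd=t_pd, t_mix=t_mix,
            t_resp=pattern.t_resp, t_ins=pattern.t_ins,
            v_ads=v_ads, v_co2=v_co2,
        )
        return _co2_volume(pattern, prof) - v_co2

    g_hi = g(span)
    if g_hi > 0:
        raise ParameterInconsistencyError(
            "v_co2 too small: even a ramp spanning the whole expiration "
            f"carries {g_hi + v_co2:.6g} liter of CO2"
        )
    g_lo = g(0.0)
    if g_lo < 0:  # excluded by the ceiling check above, defensive
        raise ParameterInconsistencyError("v_co2 not reachable with any ramp length")
    t_mix = 0.0 if g_lo == 0.0 else brentq(g, 0.0, span, xtol=_TIME_TOL)
    return float(t_pd), float(t_mix)


def fit_profile(
    pattern: BreathingPattern,
    phi_amb: float,
    phi_alv: float,
    v_ads: float,
    v_co2: float,
) -> ExpiredGasProfile:
    """Convenience wrapper: fit the transition times and build the profile."""
    t_pd, t_mix = fit_transition_times(pattern, phi_amb, phi_alv, v_ads, v_co2)
    return ExpiredGasProfile(
        phi_amb=phi_amb, phi_alv=phi_alv, t_pd=t_pd, t_mix=t_mix,
        t_resp=pattern.t_resp, t_ins=pattern.t_ins, v_ads=v_ads, v_co2=v_co2,
    )


def constraint_residuals(
    pattern: BreathingPattern, profile: ExpiredGasProfile
) -> tuple[float, float]:
    """(dead-space, CO2-volume) constraint residuals in liter, for reporting."""
    r_ads = pattern.expired_volume(profile.t_pd) - profile.v_ads
    r_co2 = _co2_volume(pattern, profile) - profile.v_co2
    return float(r_ads), float(r_co2)
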