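"""Synthetic quiet-breathing airflow waveform.

Generates the periodic nostril airflow of quiet nasal breathing as a pair of
per-phase cubic splines through a small set of control points, rescaled in
time from a template breathing frequency to a target frequency and
amplitude-normalized so that each phase of the *interpolated* waveform
integrates to exactly the target tidal volume.

Sign convention: flow > 0 during expiration (air leaving the nostrils into
the mask dead space), flow < 0 during inspiration.  The waveform is zero at
inspiration onset, at the inspiration/expiration boundary and at end of
expiration, and is extended periodically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import WaveformError

__all__ = ["WaveformTemplate", "BreathingPattern", "DEFAULT_TEMPLATE", "build_pattern"]


@dataclass(frozen=True)
class WaveformTemplate:
    """Control points of one full breath, starting at inspiration onset.

    Times are in seconds at the template's own breathing frequency; flows in
    L/s with the expiration-positive sign convention.  Both phases must start
    and end at exactly zero flow.
    """

    inspiration: tuple[tuple[float, float], ...]
    expiration: tuple[tuple[float, float], ...]
    frequency: float  # breaths per minute


#: Quiet nasal breathing at 12 breaths/min (5 s period: 2 s in, 3 s out).
#: Early-phase peaks with smooth decay toward the phase boundaries; after
#: normalization to 0.5 L tidal volume the peak inspiratory flow is
#: ~0.52 L/s (~31 L/min) and the expiratory peak sits in the first half of
#: expiration, both typical of resting adult breathing.
DEFAULT_TEMPLATE = WaveformTemplate(
    inspiration=(
        (0.0, 0.0),
        (0.25, -0.50),
        (0.60, -0.56),
        (1.00, -0.30),
        (1.40, -0.12),
        (2.0, 0.0),
    ),
    expiration=(
        (2.0, 0.0),
        (2.4, 0.32),
        (3.0, 0.28),
        (4.0, 0.15),
        (5.0, 0.0),
    ),
    frequency=12.0,
)


@dataclass
class BreathingPattern:
    """Periodic nostril airflow waveform (L/s, expiration positive)."""

    t_resp: float  # cycle period, s
    t_ins: float  # inspiration duration, s
    t_exp: float  # expiration duration, s
    v_tid: float  # tidal volume, liter
    frequency: float  # breaths per minute
    control_points_ins: tuple[tuple[float, float], ...]  # time-scaled, unnormalized
    control_points_exp: tuple[tuple[float, float], ...]
    amplitude_ins: float  # per-phase normalization factor, dimensionless
    amplitude_exp: float
    _spline_ins: CubicSpline = field(repr=False)
    _spline_exp: CubicSpline = field(repr=False)

    def flow(self, t):
        """Airflow (L/s) at time t (s); accepts scalars or arrays, periodic."""
        if np.ndim(t) == 0:
            m = float(t) % self.t_resp
            spline = self._spline_ins if m < self.t_ins else self._spline_exp
            return float(spline(m))
        t = np.asarray(t, dtype=float)
        m = np.mod(t, self.t_resp)
        return np.where(m < self.t_ins, self._spline_ins(np.minimum(m, self.t_ins)),
                        self._spline_exp(np.maximum(m, self.t_ins)))

    def expired_volume(self, t: float) -> float:
        """Cumulative expired volume (liter) from start of expiration to t.

        t must lie in [t_ins, t_resp] of the base cycle.
        """
        if not self.t_ins <= t <= self.t_resp:
            raise ValueError(f"t={t} outside expiration [{self.t_ins}, {self.t_resp}]")
        anti = self._spline_exp.antiderivative()
        return float(anti(t) - anti(self.t_ins))

    def peak_flow(self, n: int = 20001) -> float:
        """Maximum |flow| over one cycle (L/s), by dense sampling."""
        t = np.linspace(0.0, self.t_resp, n)
        return float(np.max(np.abs(self.flow(t))))

    def sample(self, n: int = 501) -> np.ndarray:
        """(n, 2) array of [t_s, flow_L_per_s] over one cycle."""
        t = np.linspace(0.0, self.t_resp, n)
        return np.column_stack([t, self.flow(t)])


def _validate_phase(points, name, sign):
    times = np.array([p[0] for p in points], dtype=float)
    flows = np.array([p[1] for p in points], dtype=float)
    if len(points) < 3:
        raise WaveformError(f"{name}: need at least 3 control points")
    if np.any(np.diff(times) <= 0):
        raise WaveformError(f"{name}: control-point times must be strictly increasing")
    if flows[0] != 0.0 or flows[-1] != 0.0:
        raise WaveformError(f"{name}: flow must be exactly 0 at phase boundaries")
    interior = flows[1:-1]
    if np.any(sign * interior < 0):
        raise WaveformError(f"{name}: interior control points must not change sign")
    return times, flows


def _phase_spline(times, flows, name, sign):
    """Natural cubic spline through the phase knots, with a sign-purity check."""
    spline = CubicSpline(times, flows, bc_type="natural")
    probe = np.linspace(times[0], times[-1], 2001)[1:-1]
    vals = sign * spline(probe)
    if np.any(vals < -1e-12):
        raise WaveformError(
            f"{name}: interpolated waveform changes sign inside the phase; "
            "adjust the control points"
        )
    return spline


def build_pattern(
    template: WaveformTemplate = DEFAULT_TEMPLATE,
    target_frequency: float = 12.0,
    target_tidal_volume: float = 0.5,
) -> BreathingPattern:
    """Rescale a template breath to a target frequency and tidal volume.

    All template times are multiplied by ``template.frequency /
    target_frequency`` (a slower target breath stretches the cycle), the
    per-phase splines are built on the stretched knots, and one amplitude
    constant per phase is then chosen so each phase integral of the
    *interpolated* waveform equals ``target_tidal_volume`` exactly — this
    absorbs any area the spline adds or removes between control points.
    """
    if template.frequency <= 0 or target_frequency <= 0:
        raise WaveformError("breathing frequencies must be positive")
    if target_tidal_volume <= 0:
        raise WaveformError("tidal volume must be positive")

    stretch = template.frequency / target_frequency
    t_ins_raw, f_ins = _validate_phase(template.inspiration, "inspiration", -1.0)
    t_exp_raw, f_exp = _validate_phase(template.expiration, "expiration", +1.0)
    if t_ins_raw[-1] != t_exp_raw[0]:
        raise WaveformError("expiration must start where inspiration ends")
    if t_ins_raw[0] != 0.0:
        raise WaveformError("template must start at t = 0")

    t_ins_k = t_ins_raw * stretch
    t_exp_k = t_exp_raw * stretch
    t_ins = float(t_ins_k[-1])
    t_resp = float(t_exp_k[-1])
    t_exp = t_resp - t_ins

    amps = []
    splines = []
    for times, flows, name, sign, in ((t_ins_k, f_ins, "inspiration", -1.0),
                                      (t_exp_k, f_exp, "expiration", +1.0)):
        raw = CubicSpline(times, flows, bc_type="natural")
        anti = raw.antiderivative()
        integral = float(anti(times[-1]) - anti(times[0]))
        if abs(integral) < 1e-12:
            raise WaveformError(f"{name}: template phase integral is zero, cannot normalize")
        amp = sign * target_tidal_volume / integral
        if amp <= 0:
            raise WaveformError(f"{name}: template phase has the wrong net sign")
        splines.append(_phase_spline(times, amp * flows, name, sign))
        amps.append(amp)

    return BreathingPattern(
        t_resp=t_resp,
        t_ins=t_ins,
        t_exp=t_exp,
        v_tid=target_tidal_volume,
        frequency=target_frequency,
        control_points_ins=tuple((float(t), float(f)) for t, f in zip(t_ins_k, f_ins)),
        control_points_exp=tuple((float(t), float(f)) for t, f in zip(t_exp_k, f_exp)),
        amplitude_ins=amps[0],
        amplitude_exp=amps[1],
        _spline_ins=splines[0],
        _spline_exp=splines[1],
    )
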