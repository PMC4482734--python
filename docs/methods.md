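# Methods

## Scope and model structure

`maskco2` answers one question at desk scale: how much CO₂ does the wearer
of a filtering facepiece respirator rebreathe over the quiet-breathing
cycle, and how much does an active venting system (AVS) — a one-way valve
plus a small centrifugal blower — reduce it. The full problem is a
turbulent, species-transporting flow in the mask dead space; this package
replaces the spatial fields with a lumped closure and keeps everything
else: the breathing waveform, the expired-CO₂ profile, the Darcy filter,
the fan characteristic, and the steady-periodic cycle analysis.

The dead space (V_ds = 0.1 L) is one well-mixed compartment whose CO₂
volume fraction φ(t) follows a linear balance of quasi-steady flows. The
closure rests on the same leading-order assumptions as the resolved
problem: CO₂ is dilute (volume fraction = molar fraction), the flow is
incompressible and isothermal, pressure excursions (≈30 Pa peak across the
filter) are negligible against 1 atm, and the ambient is well ventilated so
vented CO₂ never returns. Gas-phase diffusion through the filter during
the zero-flow instants is neglected — transport is advection-dominated
everywhere the compartment model distinguishes.

## Breathing waveform

Quiet nasal breathing is represented by per-phase natural cubic splines
through a small set of control points, one full breath starting at
inspiration onset, expiration-positive. Building a pattern involves two
operations:

* **time rescaling** — all template times are multiplied by
  (template frequency)/(target frequency), so a 15 breaths min⁻¹ template
  becomes the 5 s cycle (2 s in / 3 s out) of 12 breaths min⁻¹ breathing;
* **amplitude normalization** — one multiplicative constant per phase,
  computed *after* splining from the spline's exact antiderivative, so each
  phase of the interpolated waveform integrates to the tidal volume
  (0.5 L) to machine precision. Normalizing after interpolation absorbs
  whatever area the spline adds or removes between control points.

The default control points are this package's own design (the underlying
experimental curve is published only as a figure, which we do not treat as
ground truth): an early-phase peak and smooth decay in each phase, zero
flow clamped at the three phase boundaries, and a normalized peak
inspiratory flow of ≈0.52 L s⁻¹ (≈31 L min⁻¹) — a standard resting peak
inspiratory flow, and the value consistent with the ≈30 Pa peak filter
pressure drop that the flow model's small-pressure assumption quotes. The
expiratory peak falls at ≈2.6 s, in the first half of expiration. If the
normalized spline changes sign inside a phase the builder raises rather
than clipping, because a sign flip would corrupt the compartment's
inflow/outflow bookkeeping.

## Expired-CO₂ profile

Expired air is modelled as three segments: ambient-level air while the
anatomic dead space (V_ads = 0.15 L) empties, a linear ramp of duration
t_mix (half-open interval [t_pd, t_pd + t_mix)), then the alveolar plateau
(φ_alv = 5.3%). The transition times are not free parameters:

* t_pd solves ∫ V̇_exp dt = V_ads from expiration onset, using the exact
  spline antiderivative and Brent root finding (xtol 1e-9 s);
* t_mix solves ∫ V̇_exp φ_exp dt = V_CO2 = 0.018 L over the expiration,
  by Brent on the (strictly decreasing) ramp-length map with adaptive
  quadrature (abs. tol. 1e-9 L).

Both residuals close below 1e-6 L (in practice ~1e-13 L). Feasibility
requires V_CO2 < φ_alv (V_tid − V_ads) + φ_amb V_ads; with the default
physiology 0.018 < 0.01861 L, so a positive ramp exists. For the default
waveform the fit gives t_pd = 2.672 s and t_mix = 0.0732 s, verified
against a brute-force fine-grid cumulative integration. Rebreathed CO₂ is
deliberately not fed back into φ_exp: the first expired air is ambient-level
regardless of what was just inspired, mirroring the constitutive form the
model is built around.

## Filter, fan and operating point

The filter is a Darcy sheet, Δp = Q/G with G = κA/(μL_f). κ is obtained by
inverting the Darcy law against the manufacturer card (10 mmAq at
85 L min⁻¹ over 100 cm²; 1 mmAq = 9.80665 Pa), giving
κ = 3.431 × 10⁻¹¹ m². Only the ratio κ/L_f is physical at the lumped
level; the sheet thickness of 1.25 mm is chosen so the printed permeability
scale is reproduced. Conductance scales linearly with face area from the
100 cm² card to the mask filters (137.5 cm² standard, 132 cm² with AVS).

The blower is the clamped linear characteristic
p_fan = max(a − bQ_fan, 0) with a = 67.1 Pa, b = 1.6216 × 10⁵ Pa s m⁻³ and
a 5.5 cm² outlet. The lumped operating point assumes one uniform mask gauge
pressure p_m = −p_fan (the fan sucks the dead space below ambient); the
filter then admits ambient air at G p_fan and mass balance closes the fan
flow, Q_fan = (V̇_resp + Ga)/(1 + Gb). Two degenerate branches complete the
map: past free delivery the pressure clamps to zero and the fan exhausts
the full expiratory flow; and when inspiration overpowers the fan
(V̇_resp < −Ga) the one-way valve shuts, pinning the fan at zero flow while
the filter carries everything like a passive mask. The valve-shut branch —
rather than an error — is what lets the AVS model degenerate continuously
to the standard mask as a → 0; with the default constants neither branch is
reached during quiet breathing. At rest the operating point is
3.13 × 10⁻⁴ m³ s⁻¹ (18.8 L min⁻¹) at 16.4 Pa, verified against a
brute-force pressure scan.

## Compartment balance and the jet-capture fraction

Standard mask: during expiration the nostrils inject V̇_resp at φ_exp and
the filter vents the same flow at the mixed fraction; during inspiration
the filter admits ambient and the nostrils withdraw mixed air. With the
AVS the operating point sets the flows at every instant, and a fraction η
of the expired stream bypasses the mixed zone straight into the blower —
the minimal lumped surrogate for the resolved picture in which the blower
swallows the expiratory jet directly. η is exposed, logged and calibrated,
never hard-coded: bisection on the (monotone) steady-periodic
end-of-expiration value, default target 0.4%, tolerance 1e-4 percentage
points, yields η = 0.602 for the default card. A single mixed zone with a
bypass was preferred over two coupled zones as the simplest closure that
can reproduce the target end value.

## Numerics

The cycle ODE is integrated segment-wise with DOP853 (rtol 1e-10,
atol 1e-13, max step 0.01 s), with forced segment edges at the phase
boundaries and at t_pd and t_pd + t_mix so the ≈0.07 s mixing ramp is never
stepped over. Output is sampled at 5 ms (1002 points per 5 s cycle);
summary integrals use the trapezoidal rule on that grid, except the CO₂
bookkeeping check, which integrates the dense solution with adaptive
quadrature to close below 1e-6 relative. The steady-periodic state is the
fixed point of the cycle map; because the ODE is linear the map is affine
and the fixed-point iteration (tolerance 1e-8 absolute on φ₀, cap 200
cycles) converges in 2–3 cycles — the contraction factor is
exp(−2V_tid/V_ds) ≈ 4.5 × 10⁻⁵ for the standard mask. Fractions are carried
dimensionless throughout; percent appears only at I/O boundaries.

## What the generator emulates — and what it does not

The synthetic waveform reproduces the *structure* of measured quiet
breathing (phase durations, exact phase volumes, early peaks, spline
smoothness) but not any particular subject's samples; breath-to-breath
variability, mouth breathing and exercise hyperpnea are out of scope. The
compartment model reproduces volume-and-time-averaged CO₂ levels, not
spatial fields: the resolved AVS solution shows a ≈2% transient peak whose
timing depends on jet-blower geometry that a lumped model cannot carry, so
only the end-of-expiration value, the cycle average and the inspired
average are quantitative outputs here. Passing tests therefore support the
averaged quantities, not local concentrations at the nostrils or on the
filter surface. For the default card the model gives: standard mask — end
of expiration 5.12%, cycle average 2.33%, inspired 1.05%; AVS — cycle
average 0.58%, inspired 0.077%. The cycle averages sit below the resolved
reference values (3% and 0.3%) because a single mixed zone spreads the
late-expiration CO₂ front over the whole dead space; both lie within the
surrogate tolerances the tests assert (±1 pp, factor 2).

## Known limitations

* η compensates for unresolved jet capture and is meaningful only after
  calibration against a resolved or measured end-expiration level.
* The one-way valve is folded into the fan curve; valve dynamics
  (cracking pressure, flutter) are not modelled.
* Filter loading, humidity, heat and O₂ depletion are out of scope.
* The fan curve is quasi-steady; blower inertia is ignored.
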