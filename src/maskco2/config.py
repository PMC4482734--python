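"""Run configuration and the end-to-end pipeline.

The configuration is a nested YAML document with sections mirroring the
physical components (respiration, gas, filter, fan, mask, capture, solver).
Every parameter has a default — an empty file is a valid configuration for
the standard mask — unknown keys are rejected with their key path, and the
fan section may be set to ``null`` to model a mask that physically has no
blower (an error if mode is "avs").

``run_pipeline`` orchestrates the full analysis: build the breathing
waveform, fit the expired-gas transition times, fit the filter permeability,
solve the steady-periodic cycle for the requested mask variant, and compute
the summary fractions and closed-form estimates.  Outputs are deterministic;
the seed field is reserved (no stage currently draws random numbers).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import compartment, components, estimates, expired_gas, respiration
from .errors import ConfigError

__all__ = ["RunConfig", "load_config", "run_pipeline"]

log = logging.getLogger("maskco2")


@dataclass
class RespirationConfig:
    tidal_volume_l: float = 0.5
    frequency_bpm: float = 12.0
    template_frequency_bpm: float = 12.0
    template_inspiration: list = field(
        default_factory=lambda: [list(p) for p in
                                 respiration.DEFAULT_TEMPLATE.inspiration])
    template_expiration: list = field(
        default_factory=lambda: [list(p) for p in
                                 respiration.DEFAULT_TEMPLATE.expiration])


@dataclass
class GasConfig:
    phi_amb: float = 0.0004
    phi_alv: float = 0.053
    v_ads_l: float = 0.15
    v_co2_l: float = 0.018


@dataclass
class FilterConfig:
    spec_dp_mmaq: float = 10.0
    spec_flow_lpm: float = 85.0
    spec_area_cm2: float = 100.0
    thickness_mm: float = 1.25
    mu_pa_s: float = 1.9e-5
    porosity: float = 0.88
    area_standard_cm2: float = 137.5
    area_avs_cm2: float = 132.0


@dataclass
class FanConfig:
    a_pa: float = 67.1
    b_pa_s_m3: float = 1.6216e5
    outlet_area_cm2: float = 5.5


@dataclass
class MaskSection:
    dead_space_l: float = 0.1
    nostril_area_cm2: float = 0.98  # reporting only
    air_density_kg_m3: float = 1.1  # reporting only


@dataclass
class CaptureConfig:
    policy: str = "calibrate"  # "calibrate" | "fixed"
    eta: float = 0.0  # used when policy == "fixed"
    target_end_expiration_pct: float = 0.4  # used when policy == "calibrate"


@dataclass
class SolverConfig:
    periodic_tol: float = 1e-8
    max_cycles: int = 200
    max_step_s: float = 0.01
    grid_step_s: float = 0.005


@dataclass
class RunConfig:
    mode: str = "standard"  # "standard" | "avs"
    respiration: RespirationConfig = field(default_factory=RespirationConfig)
    gas: GasConfig = field(default_factory=GasConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    fan: FanConfig | None = field(default_factory=FanConfig)
    mask: MaskSection = field(default_factory=MaskSection)
    capture: CaptureConfig = field(default_factory=CaptureConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)
    seed: int = 0  # reserved; the pipeline is deterministic

    def validate(self) -> "RunConfig":
        if self.mode not in ("standard", "avs"):
            raise ConfigError(f"mode must be 'standard' or 'avs', got {self.mode!r}")
        if self.mode == "avs" and self.fan is None:
            raise ConfigError("mode 'avs' requires a fan section")
        positives = {
            "respiration.tidal_volume_l": self.respiration.tidal_volume_l,
            "respiration.frequency_bpm": self.respiration.frequency_bpm,
            "respiration.template_frequency_bpm": self.respiration.template_frequency_bpm,
            "gas.phi_alv": self.gas.phi_alv,
            "gas.v_ads_l": self.gas.v_ads_l,
            "gas.v_co2_l": self.gas.v_co2_l,
            "filter.spec_dp_mmaq": self.filter.spec_dp_mmaq,
            "filter.spec_flow_lpm": self.filter.spec_flow_lpm,
            "filter.spec_area_cm2": self.filter.spec_area_cm2,
            "filter.thickness_mm": self.filter.thickness_mm,
            "filter.mu_pa_s": self.filter.mu_pa_s,
            "filter.area_standard_cm2": self.filter.area_standard_cm2,
            "filter.area_avs_cm2": self.filter.area_avs_cm2,
            "mask.dead_space_l": self.mask.dead_space_l,
            "solver.periodic_tol": self.solver.periodic_tol,
        }
        if self.fan is not None:
            positives["fan.b_pa_s_m3"] = self.fan.b_pa_s_m3
            positives["fan.outlet_area_cm2"] = self.fan.outlet_area_cm2
        for path, value in positives.items():
            if not value > 0:
                raise ConfigError(f"{path} must be positive, got {value}")
        if self.gas.phi_amb < 0 or not self.gas.phi_amb < self.gas.phi_alv <= 1:
            raise ConfigError("need 0 <= gas.phi_amb < gas.phi_alv <= 1")
        if self.capture.policy not in ("calibrate", "fixed"):
            raise ConfigError("capture.policy must be 'calibrate' or 'fixed'")
        if not 0.0 <= self.capture.eta <= 1.0:
            raise ConfigError("capture.eta must lie in [0, 1]")
        return self


_SECTIONS = {
    "respiration": RespirationConfig,
    "gas": GasConfig,
    "filter": FilterConfig,
    "fan": FanConfig,
    "mask": MaskSection,
    "capture": CaptureConfig,
    "solver": SolverConfig,
}


def _build_section(cls, data, path):
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(data).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} under '{path}'")
    return cls(**data)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML run configuration; defaults fill every gap."""
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError("top level of the config must be a mapping")
    unknown = set(raw) - set(_SECTIONS) - {"mode", "seed"}
    if unknown:
        raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}")
    kwargs = {}
    for key, cls in _SECTIONS.items():
        if key not in raw:
            continue
        if raw[key] is None:
            if key != "fan":
                raise ConfigError(f"section '{key}' may not be null")
            kwargs[key] = None
        else:
            kwargs[key] = _build_section(cls, raw[key], key)
    if "mode" in raw:
        kwargs["mode"] = raw["mode"]
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    return RunConfig(**kwargs).validate()


def build_model(config: RunConfig):
    """Construct (pattern, profile, mask_config) from a validated RunConfig.

    The capture fraction is left at the configured fixed value; calibration
    happens in run_pipeline where the target is known.
    """
    r = config.respiration
    template = respiration.WaveformTemplate(
        inspiration=tuple(tuple(p) for p in r.template_inspiration),
        expiration=tuple(tuple(p) for p in r.template_expiration),
        frequency=r.template_frequency_bpm,
    )
    pattern = respiration.build_pattern(template, r.frequency_bpm, r.tidal_volume_l)
    profile = expired_gas.fit_profile(
        pattern, config.gas.phi_amb, config.gas.phi_alv,
        config.gas.v_ads_l, config.gas.v_co2_l,
    )
    f = config.filter
    kappa = components.fit_permeability(
        f.spec_dp_mmaq, f.spec_flow_lpm, f.spec_area_cm2 * 1e-4,
        f.thickness_mm * 1e-3, f.mu_pa_s,
    )
    area = (f.area_avs_cm2 if config.mode == "avs" else f.area_standard_cm2) * 1e-4
    filt = components.FilterModel(kappa, area, f.thickness_mm * 1e-3,
                                  f.mu_pa_s, f.porosity)
    fan = None
    if config.mode == "avs":
        fan = components.FanModel(config.fan.a_pa, config.fan.b_pa_s_m3,
                                  config.fan.outlet_area_cm2 * 1e-4)
    eta = config.capture.eta if config.mode == "avs" else 0.0
    mask = compartment.MaskConfig(
        v_ds=config.mask.dead_space_l, filter=filt, fan=fan,
        eta=eta, phi_amb=config.gas.phi_amb,
    )
    return pattern, profile, mask


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full analysis for one mask variant; optionally write CSVs.

    Returns a flat summary record (fractions dimensionless; times s;
    kappa m^2).  When ``out_dir`` is given, writes ``waveform.csv``,
    ``cycle_<mode>.csv`` and ``summary_<mode>.csv`` there.
    """
    config.validate()
    pattern, profile, mask = build_model(config)
    log.info("waveform: period %.3f s (ins %.3f s / exp %.3f s), tidal %.3f L",
             pattern.t_resp, pattern.t_ins, pattern.t_exp, pattern.v_tid)
    res_ads, res_co2 = expired_gas.constraint_residuals(pattern, profile)
    log.info("expired-gas fit: t_pd=%.6f s, t_mix=%.6e s "
             "(residuals %.2e / %.2e liter)", profile.t_pd, profile.t_mix,
             res_ads, res_co2)
    log.info("filter: kappa=%.4e m^2, conductance=%.4e m^3/(s Pa)",
             mask.filter.kappa, mask.filter.conductance)

    eta = mask.eta
    if config.mode == "avs" and config.capture.policy == "calibrate":
        target = config.capture.target_end_expiration_pct / 100.0
        eta = compartment.calibrate_capture_fraction(
            mask, pattern, profile, target,
            tol=config.solver.periodic_tol * 100,
            max_cycles=config.solver.max_cycles,
        )
        mask = mask.with_eta(eta)
        log.info("capture fraction calibrated: eta=%.6f for end-expiration "
                 "target %.4f%%", eta, config.capture.target_end_expiration_pct)

    sol = compartment.solve_steady_periodic(
        mask, pattern, profile,
        tol=config.solver.periodic_tol, max_cycles=config.solver.max_cycles,
        max_step=config.solver.max_step_s, grid_step=config.solver.grid_step_s,
    )
    log.info("steady periodic after %d cycles: phi0=%.6f%%", sol.cycles,
             100 * sol.phi_start)

    end_val = compartment.end_expiration_value(sol)
    est = estimates.inspired_fraction_estimate(
        end_val, config.mask.dead_space_l, config.respiration.tidal_volume_l,
        config.gas.phi_amb,
    )
    peak_q = pattern.peak_flow() / 1000.0  # m^3/s
    summary = {
        "mode": config.mode,
        "phi0": sol.phi_start,
        "end_expiration": end_val,
        "time_average": compartment.time_average(sol),
        "inspired_average": compartment.inspired_average(sol, pattern),
        "inspired_estimate_exact": est.exact,
        "inspired_estimate_simplified": est.simplified,
        "eta": eta,
        "cycles_to_convergence": sol.cycles,
        "t_pd_s": profile.t_pd,
        "t_mix_s": profile.t_mix,
        "fit_residual_ads_l": res_ads,
        "fit_residual_co2_l": res_co2,
        "kappa_m2": mask.filter.kappa,
        "peak_filter_dp_pa": components.filter_pressure_drop(mask.filter, peak_q),
    }
    for key, value in summary.items():
        if key != "mode":
            log.info("summary %s = %.6g", key, value)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        wf = pattern.sample(1001)
        pd.DataFrame(wf, columns=["t_s", "flow_L_per_s"]).to_csv(
            out / "waveform.csv", index=False, float_format="%.10g")
        pd.DataFrame({
            "t_s": sol.t,
            "phi": sol.phi,
            "fan_flow_m3s": sol.fan_flow,
            "filter_flow_m3s": sol.filter_flow,
            "mask_gauge_Pa": sol.mask_gauge,
        }).to_csv(out / f"cycle_{config.mode}.csv", index=False,
                  float_format="%.10g")
        pd.DataFrame([summary]).to_csv(out / f"summary_{config.mode}.csv",
                                       index=False, float_format="%.10g")
    return summary
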