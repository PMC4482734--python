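"""Shared fixtures: default breathing pattern, fitted gas profile, component
models and the (expensive) steady-periodic solutions, built once per session."""

import pytest

import maskco2 as m

# Parameter card used throughout: quiet breathing of a young adult,
# 0.5 L tidal volume at 12 breaths/min, 0.15 L anatomic dead space,
# 5.3% alveolar CO2, 0.018 L CO2 per expiration, 0.04% ambient,
# 0.1 L mask dead space.
PHI_AMB = 0.0004
PHI_ALV = 0.053
V_ADS = 0.15
V_CO2 = 0.018
V_DS = 0.1
V_TID = 0.5


@pytest.fixture(scope="session")
def pattern():
    return m.build_pattern()


@pytest.fixture(scope="session")
def profile(pattern):
    return m.fit_profile(pattern, PHI_AMB, PHI_ALV, V_ADS, V_CO2)


@pytest.fixture(scope="session")
def spec_filter():
    kappa = m.fit_permeability(10.0, 85.0, 0.01, 1.25e-3, 1.9e-5)
    return m.FilterModel(kappa, 0.01, 1.25e-3, 1.9e-5, 0.88)


@pytest.fixture(scope="session")
def std_filter(spec_filter):
    return spec_filter.with_area(137.5e-4)


@pytest.fixture(scope="session")
def avs_filter(spec_filter):
    return spec_filter.with_area(132e-4)


@pytest.fixture(scope="session")
def fan():
    return m.FanModel()


@pytest.fixture(scope="session")
def std_mask(std_filter):
    return m.MaskConfig(v_ds=V_DS, filter=std_filter, phi_amb=PHI_AMB)


@pytest.fixture(scope="session")
def avs_mask(avs_filter, fan):
    return m.MaskConfig(v_ds=V_DS, filter=avs_filter, fan=fan, phi_amb=PHI_AMB)


@pytest.fixture(scope="session")
def std_solution(std_mask, pattern, profile):
    return m.solve_steady_periodic(std_mask, pattern, profile)


@pytest.fixture(scope="session")
def eta_calibrated(avs_mask, pattern, profile):
    """Capture fraction reproducing the 0.4% AVS end-of-expiration level."""
    return m.calibrate_capture_fraction(avs_mask, pattern, profile, 0.004)


@pytest.fixture(scope="session")
def avs_solution(avs_mask, pattern, profile, eta_calibrated):
    return m.solve_steady_periodic(avs_mask.with_eta(eta_calibrated),
                                   pattern, profile)
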