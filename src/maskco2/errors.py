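"""Exception hierarchy for the mask CO2 model."""


class MaskCO2Error(Exception):
    """Base class for all model errors."""


class WaveformError(MaskCO2Error, ValueError):
    """Invalid breathing-waveform template or a sign flip inside a phase."""


class ParameterInconsistencyError(MaskCO2Error, ValueError):
    """Physiological parameters admit no solution for a fitted quantity."""


class ModelLimitError(MaskCO2Error, RuntimeError):
    """The lumped closure is outside its domain of validity."""


class ConvergenceError(MaskCO2Error, RuntimeError):
    """The steady-periodic iteration failed to converge."""


class CalibrationError(MaskCO2Error, ValueError):
    """Calibration target lies outside the achievable bracket."""


class ConfigError(MaskCO2Error, ValueError):
    """Invalid or inconsistent run configuration."""
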