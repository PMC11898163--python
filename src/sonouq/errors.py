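"""Exception hierarchy shared across the package."""


class SonoUQError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SonoUQError):
    """A spec, config or geometry description is internally inconsistent."""


class TissueLookupError(SonoUQError, KeyError):
    """A tissue label or name is absent from the property table."""


class UnsupportedPropertyError(SonoUQError):
    """An acoustic property cannot be treated as uncertain (attenuation)."""


class StabilityError(SonoUQError):
    """Solver settings violate the CFL stability bound."""


class GeometryError(SonoUQError):
    """The transducer does not fit the computational domain."""


class CalibrationError(SonoUQError):
    """Source calibration is degenerate (zero free-water peak)."""


class EvaluationError(SonoUQError):
    """Accuracy metrics were requested on invalid inputs (empty mask etc.)."""
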