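"""Exception hierarchy shared across the pipeline stages."""


class DabquantError(Exception):
    """Base class for all errors raised by dabquant."""


class FormatError(DabquantError):
    """An input file or array does not have the required layout."""


class ShapeError(DabquantError):
    """Two rasters that must share a frame have different shapes."""


class ConfigError(DabquantError):
    """Invalid configuration, e.g. a singular stain matrix."""


class ParameterError(DabquantError):
    """A numeric parameter is outside its admissible range."""


class CalibrationError(DabquantError):
    """The calibration set cannot support threshold optimisation."""


class OptionalDependencyError(DabquantError):
    """An optional external tool is configured but not installed."""


class UndefinedScoreError(DabquantError):
    """Scoring was requested on an image with zero detected nuclei."""


class CapacityError(DabquantError):
    """The synthetic generator could not place the requested nuclei."""
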