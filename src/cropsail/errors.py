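"""Exception hierarchy shared across the package."""


class CropsailError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CropsailError):
    """An invalid configuration value; the message names the offending field."""


class SchemaError(CropsailError):
    """Input does not match the expected column/feature schema."""


class ParseError(CropsailError):
    """A value in a columnar text file could not be parsed."""


class DegenerateStateError(CropsailError):
    """A crop state that cannot be coupled (e.g. zero leaf area)."""


class CouplingDomainError(CropsailError):
    """A transformation formula was evaluated outside its valid domain."""


class GeometryDomainError(CropsailError):
    """Solar-geometry input outside the valid domain (e.g. DOY out of range)."""


class NightTimeError(GeometryDomainError):
    """The sun is at or below the horizon for the requested configuration."""


class UndefinedAzimuthError(GeometryDomainError):
    """Solar azimuth undefined (sun at zenith with nonzero hour angle)."""


class ForwardModelError(CropsailError):
    """A forward-model parameter is outside the admissible domain."""


class DatasetError(CropsailError):
    """Dataset construction or splitting failure."""


class FitError(CropsailError):
    """Predictor fitting or prediction failure."""


class LayoutError(CropsailError):
    """Invalid raster/plot layout (overlap, out of bounds, empty plot)."""
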