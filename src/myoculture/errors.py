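"""Exception hierarchy shared across the package."""


class MyocultureError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(MyocultureError, ValueError):
    """Invalid simulation or processing parameters."""


class FormatError(MyocultureError, ValueError):
    """Malformed or inconsistent image/table input."""


class GeometryError(MyocultureError, ValueError):
    """Requested geometry does not fit the image."""


class DataError(MyocultureError, ValueError):
    """Inconsistent per-object data (duplicate labels, mixed provenance...)."""


class ConsistencyError(MyocultureError, ValueError):
    """Counts violate an arithmetic constraint (e.g. numerator > denominator)."""


class ConfigError(MyocultureError, ValueError):
    """Invalid or incomplete run configuration."""


class FittingError(MyocultureError, ValueError):
    """Regression model cannot be estimated on the given table."""


class PlacementError(MyocultureError, RuntimeError):
    """Scene objects could not be placed without violating spacing rules."""
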