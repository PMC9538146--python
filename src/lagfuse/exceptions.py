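"""Exception hierarchy shared across the package."""


class LagfuseError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(LagfuseError, ValueError):
    """A configuration object or parameter set is invalid."""


class DegenerateInputError(LagfuseError, ValueError):
    """Input is degenerate for the requested operation (e.g. constant
    signal where a min-max range is required)."""


class BoundaryError(LagfuseError, IndexError):
    """A requested window or span falls outside the available samples."""


class OnsetNotFoundError(LagfuseError, LookupError):
    """No activation onset crossing was found in the signal."""


class StratificationError(LagfuseError, ValueError):
    """A cross-validation fold cannot represent every class."""


class ShapeError(LagfuseError, ValueError):
    """Array arguments have mutually inconsistent shapes."""
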