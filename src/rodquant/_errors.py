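"""Exception types shared across the package."""


class RodquantError(Exception):
    """Base class for all package errors."""


class CapacityError(RodquantError):
    """Requested cell density cannot be placed without overlaps."""


class DegenerateShapeError(RodquantError):
    """Region has no measurable elongated axis (e.g. a circle or a sliver)."""


class ConfigurationError(RodquantError):
    """Invalid or incomplete run configuration / input file."""


class NotComputableError(RodquantError):
    """A statistic cannot be computed from the given inputs (e.g. n < 2)."""
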