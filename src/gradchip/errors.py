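"""Exception hierarchy shared across the package."""


class GradChipError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(GradChipError, ValueError):
    """A value violates a domain invariant; the message names the field."""


class ConfigurationError(GradChipError, ValueError):
    """Mutually inconsistent configuration (e.g. two drugs on one channel)."""


class CapacityError(GradChipError, ValueError):
    """A request exceeds the chip's capacity (e.g. more conditions than arrays)."""


class ShapeError(GradChipError, ValueError):
    """Array/profile dimensions do not match the chip layout."""


class StabilityError(GradChipError, RuntimeError):
    """An explicit solver step size violates its stability (CFL) bound."""
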