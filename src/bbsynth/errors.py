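"""Exception types shared across the package."""


class BBSynthError(Exception):
    """Base class for all package-specific errors."""


class DegenerateInputError(BBSynthError):
    """An input volume or table has no usable structure (constant, empty, ...)."""


class PlacementError(BBSynthError):
    """Phantom objects could not be placed under the requested constraints."""


class ShapeMismatchError(BBSynthError):
    """Volumes that must share a grid do not."""
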