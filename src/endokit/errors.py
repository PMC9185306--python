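"""Exception types shared across the package."""


class EndokitError(Exception):
    """Base class for all package-specific errors."""


class ImageFormatError(EndokitError, ValueError):
    """Raised when an input raster violates a shape or channel contract."""


class ParameterError(EndokitError, ValueError):
    """Raised when an operation parameter is outside its valid range."""


class DegenerateRegionError(EndokitError, ValueError):
    """Raised when a level-set region (inside or outside) is empty.

    The message names which side collapsed.
    """


class ContractError(EndokitError, ValueError):
    """Raised when a pluggable component violates its declared contract."""


class DataError(EndokitError, ValueError):
    """Raised for malformed tabular data (labels, feature widths, splits)."""
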