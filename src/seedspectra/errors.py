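"""Exception hierarchy shared across the package."""


class SeedSpectraError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SeedSpectraError, ValueError):
    """A configuration or specification object violates its invariants."""


class FormatError(SeedSpectraError, ValueError):
    """A file on disk is malformed or internally contradictory."""


class UnsupportedDialectError(FormatError):
    """The file uses a dialect (e.g. ENVI data type) this package does not read."""


class ShapeError(SeedSpectraError, ValueError):
    """Array dimensions are incompatible with the requested operation."""


class LayoutError(SeedSpectraError, ValueError):
    """A requested scene layout does not fit the frame."""


class SplitError(SeedSpectraError, ValueError):
    """A train/test split cannot be performed as requested."""
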