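"""Exception hierarchy.

All package errors derive from :class:`HeteromapError` so callers (notably
the CLI) can catch one type and map it to a nonzero exit.
"""


class HeteromapError(Exception):
    """Base class for all errors raised by heteromap."""


class EmptySampleError(HeteromapError, ValueError):
    """A window or sample contained no valid observations."""


class ParameterError(HeteromapError, ValueError):
    """An index or window parameter is outside its domain."""


class MetricMismatchError(HeteromapError, ValueError):
    """A scalar metric was requested on tuple values, or vice versa."""


class ShapeMismatchError(HeteromapError, ValueError):
    """Aligned grids or layers do not share the same shape."""


class BandOutOfRangeError(HeteromapError, IndexError):
    """A band selection exceeds the number of bands in a file."""


class RasterIOError(HeteromapError, OSError):
    """A raster file could not be read or written."""
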