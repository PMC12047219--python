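"""Exception hierarchy shared across the toolkit."""


class RseikitError(Exception):
    """Base class for all toolkit errors."""


class RasterFormatError(RseikitError):
    """A raster file or band is malformed or missing required content."""


class AlignmentError(RseikitError):
    """Grids, transforms or coordinate systems do not match."""


class ConfigurationError(RseikitError):
    """An operation was configured inconsistently (unknown sensor, wrong
    indicator set, missing band)."""


class DegenerateDataError(RseikitError):
    """The data admit no meaningful answer (constant raster, zero valid
    pixels, rank-deficient sample)."""
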