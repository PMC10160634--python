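"""Exception hierarchy shared across the pipeline stages."""


class ChlorokinError(Exception):
    """Base class for all package errors."""


class InvalidProtocolError(ChlorokinError):
    """Measurement protocol fails validation (non-positive duration, pulse too long)."""


class LayoutCapacityError(ChlorokinError):
    """More variant replicates requested than the sowing grid holds."""


class GeometryError(ChlorokinError):
    """Image too small to draw the requested plate layout."""


class NoValidFrameError(ChlorokinError):
    """Every frame exceeds the saturation limit; no reference frame exists."""


class DegenerateInputError(ChlorokinError):
    """Input without the contrast/variance the operation requires."""


class ConfigError(ChlorokinError):
    """Missing or inconsistent configuration."""


class AlignmentError(ChlorokinError):
    """Grids or shapes that must match do not."""


class InsufficientDataError(ChlorokinError):
    """Fewer replicates or matched points than the statistic needs."""
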