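"""Exception hierarchy shared across the pipeline."""


class PlaceMapError(Exception):
    """Base class for all placemap errors."""


class InvalidArgumentError(PlaceMapError, ValueError):
    """A caller-supplied parameter is outside its documented range."""


class InvalidModelError(PlaceMapError):
    """A simulated firing-rate model is unusable (e.g. rate above the cap)."""


class EmptyMapError(PlaceMapError):
    """A rate map has no valid bins under the requested mask."""


class InsufficientDataError(PlaceMapError):
    """Not enough observations to compute the requested quantity."""


class InsufficientOverlapError(InsufficientDataError):
    """Two maps share too few commonly visited bins."""


class ProtocolError(PlaceMapError):
    """A light protocol is internally inconsistent (e.g. overlapping windows)."""


class ManifestError(PlaceMapError):
    """A session manifest is missing required entries or files."""


class RobustnessError(PlaceMapError):
    """Leave-one-animal-out robustness cannot be assessed (<3 animals)."""
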