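"""Exception hierarchy shared across the pipeline stages."""


class DbdscreenError(Exception):
    """Base class for all package-specific errors."""


class StructureParseError(DbdscreenError):
    """A structure file could not be parsed (message names the offending line)."""


class EmptyStructureError(DbdscreenError):
    """A structure file contained nothing at all."""


class ChainNotFoundError(DbdscreenError, KeyError):
    """A requested chain id is absent from the structure."""


class DomainError(DbdscreenError, ValueError):
    """An argument is outside the operation's domain."""


class EmptySiteError(DbdscreenError):
    """Consensus site construction received only empty predictions."""


class EmptyResultError(DbdscreenError):
    """An operation that requires shared inputs found none."""


class PoseFormatError(DbdscreenError):
    """A pose file violates the pose dialect (duplicate ids, bad records)."""


class PlacementError(DbdscreenError):
    """A synthetic-geometry generator could not realize the requested ground truth."""


class ConfigError(DbdscreenError):
    """A run configuration contains unknown keys or invalid values."""
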