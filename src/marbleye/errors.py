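"""Exception hierarchy for marbleye."""


class MarbleyeError(Exception):
    """Base class for all marbleye errors."""


class InvalidInputError(MarbleyeError, ValueError):
    """An input image, table, or argument violates a precondition."""


class InvalidConfigError(MarbleyeError, ValueError):
    """A configuration value or file is malformed."""


class NoRegionOfInterestError(MarbleyeError):
    """Background removal left no beef region to analyse."""


class PlacementError(MarbleyeError):
    """The phantom generator could not place the requested flecks without overlap."""
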