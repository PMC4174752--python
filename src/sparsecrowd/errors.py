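"""Exception types raised across the package."""


class SparseCrowdError(Exception):
    """Base class for package-specific errors."""


class UnknownSymbolError(SparseCrowdError, ValueError):
    """A symbol id is not one of the known glyph names."""


class BoundsError(SparseCrowdError, ValueError):
    """A glyph placement would fall outside the display image."""


class PlacementError(SparseCrowdError, RuntimeError):
    """Random flanker placement failed after the retry budget."""


class ConfigError(SparseCrowdError, ValueError):
    """An experiment configuration is invalid or inconsistent."""


class ThresholdNotReached(SparseCrowdError, RuntimeError):
    """A sampling curve never crosses the requested performance criterion."""
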