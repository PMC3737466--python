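"""Exception types shared across the package."""


class DyeswapError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(DyeswapError, ValueError):
    """Invalid generator or pipeline configuration."""


class NoUsableSpotsError(DyeswapError):
    """Spot filtering removed every spot."""


class NormalizationError(DyeswapError):
    """Array cannot be normalized (too few spots, non-finite input)."""


class ZeroVarianceError(DyeswapError):
    """Pooled trimmed variance is zero while some probe means are nonzero."""


class InputError(DyeswapError, ValueError):
    """Malformed user-supplied input (sequences, lists, tables)."""
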