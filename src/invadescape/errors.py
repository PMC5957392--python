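"""Exception types shared across the package."""


class InvadescapeError(Exception):
    """Base class for package errors."""


class ConfigurationError(InvadescapeError, ValueError):
    """Invalid configuration (proportions, trait levels, MCMC settings...)."""


class DimensionError(InvadescapeError, ValueError):
    """Raster or array dimensions too small / inconsistent for the operation."""


class FormatError(InvadescapeError, ValueError):
    """Malformed on-disk file (ASCII grid header or body)."""


class StateError(InvadescapeError, RuntimeError):
    """Corrupted simulation state (negative counts, unknown class codes)."""
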