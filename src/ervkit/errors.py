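"""Exception hierarchy shared across the package."""


class ERVKitError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ERVKitError):
    """A packaged or user-supplied configuration file is invalid."""


class InputError(ERVKitError):
    """An operation received input violating its preconditions."""


class InsufficientSitesError(ERVKitError):
    """Too few comparable alignment columns for a distance estimate."""


class SaturatedDivergenceError(ERVKitError):
    """Divergence outside the valid domain of the distance correction."""
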