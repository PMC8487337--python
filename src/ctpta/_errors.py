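"""Exception hierarchy shared across the package."""


class CtptaError(Exception):
    """Base class for package errors."""


class ParameterError(CtptaError, ValueError):
    """A model parameter is outside its mathematical domain."""


class InputError(CtptaError, ValueError):
    """User-supplied data (grids, counts, tables) is malformed."""


class ConfigurationError(CtptaError, ValueError):
    """A configuration (stratum, spec file) describes an infeasible setup."""


class InconsistencyError(CtptaError, ValueError):
    """A printed rate cannot be reconciled with any integer count."""


class AmbiguityError(CtptaError, ValueError):
    """A printed rate is consistent with more than one integer count."""
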