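"""Exception hierarchy shared across the package."""


class MMSEGroupsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MMSEGroupsError):
    """A configuration object is internally inconsistent (bad sizes, non-stochastic rows, ...)."""


class ValidationError(MMSEGroupsError):
    """Input data violate a documented precondition (score above maximum, missing category, ...)."""


class InconsistencyError(MMSEGroupsError):
    """Observed scores are consistent with no candidate scoring system."""
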