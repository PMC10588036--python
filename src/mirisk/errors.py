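"""Exception hierarchy.

Exit-code mapping used by the CLI: ValidationError / ConfigurationError -> 2,
NumericalError -> 3, anything else propagates.
"""


class MiriskError(Exception):
    """Base class for all package errors."""


class ValidationError(MiriskError):
    """Malformed or inconsistent input data."""


class ConfigurationError(MiriskError):
    """Invalid configuration (bad spec, undeclared covariate, bad threshold)."""


class NumericalError(MiriskError):
    """A computation could not be completed (non-convergence, undefined metric)."""
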