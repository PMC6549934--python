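"""Exception hierarchy shared across the package.

Three error families map onto the three ways a run can go wrong:
bad configuration files, bad input data, and data that is simply absent.
The CLI translates each family into a distinct exit code.
"""


class AquavalError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(AquavalError):
    """A configuration value violates its contract (e.g. weights not summing to 1)."""


class InvalidInputError(AquavalError):
    """Runtime input data violates a precondition (e.g. a negative concentration)."""


class MissingDataError(AquavalError):
    """A required datum is absent (e.g. a substance without an EQS entry)."""
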