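"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ValidationError -> 2, NumericError -> 3.
"""


class FuzzybaseError(Exception):
    """Base class for all package errors."""


class ValidationError(FuzzybaseError):
    """Bad user input: malformed files, out-of-range values, shape mismatches."""


class ConfigurationError(ValidationError):
    """Invalid configuration (membership-function params, training options)."""


class NumericError(FuzzybaseError):
    """Numerical failure during training or inference (non-finite loss)."""


class NotFittedError(FuzzybaseError):
    """A model was asked to score inputs before being trained."""
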