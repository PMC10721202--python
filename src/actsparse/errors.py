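"""Exception hierarchy shared across the package."""


class ActsparseError(Exception):
    """Base class for all package-specific errors."""


class DomainError(ActsparseError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class UndefinedSparsityError(DomainError):
    """Sparsity of an all-zero activation vector is undefined.

    A layer that never fires has no code inequity; returning 0 or NaN
    would silently propagate into downstream regressions.
    """


class ValidationError(ActsparseError, ValueError):
    """Input data violates a declared contract (e.g. score out of bounds)."""


class FormatError(ActsparseError, ValueError):
    """A file does not conform to the expected tabular format."""


class ConfigurationError(ActsparseError, ValueError):
    """A configuration object or request is internally inconsistent."""


class DegenerateInputError(ActsparseError, ValueError):
    """Numerically degenerate input (zero variance, constant column...)."""


class InputError(ActsparseError, OSError):
    """An input file could not be read or decoded."""
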