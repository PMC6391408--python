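"""Exception hierarchy shared across the package."""


class TNFluxError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(TNFluxError):
    """A value violates an operation precondition (non-finite, nonpositive, out of range)."""


class DegenerateDesignError(TNFluxError):
    """A regression design matrix is rank deficient (collinear or constant columns)."""


class MissingInputError(TNFluxError):
    """A required (watershed, year, model) combination or table is absent."""


class InsufficientBaselineError(TNFluxError):
    """A daily precipitation series does not cover the requested baseline period."""


class UnscalableRegionError(TNFluxError):
    """A scaling factor is undefined: zero input total against a nonzero reference."""


class ConfigurationError(TNFluxError):
    """An unknown scenario id or an inconsistent run configuration."""


class SchemaError(TNFluxError):
    """A table fails schema validation (missing column, bad type, duplicate key)."""
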