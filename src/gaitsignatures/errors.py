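"""Exception hierarchy shared across the package.

Every error raised by the library derives from :class:`GaitSigError` so that
callers (and the CLI) can map failures to a single machine-parsable category.
"""


class GaitSigError(Exception):
    """Base class for all package errors."""

    category = "error"


class FormatError(GaitSigError):
    """A file does not match the expected on-disk dialect (columns, header)."""

    category = "format"


class ValidationError(GaitSigError):
    """Data parsed fine but violates a domain invariant (NaN, bad event, ...)."""

    category = "validation"


class ConfigurationError(GaitSigError):
    """Invalid hyperparameters or run configuration (e.g. lookback rule)."""

    category = "configuration"


class ComparabilityError(GaitSigError):
    """Two objects cannot be compared (grid, basis, or shape mismatch)."""

    category = "comparability"


class DivergenceError(GaitSigError):
    """Training produced a non-finite loss."""

    category = "divergence"


class InsufficientDataError(GaitSigError):
    """Too little data for the requested operation (cycles, strides, group)."""

    category = "insufficient-data"
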