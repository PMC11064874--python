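"""Exception types shared across the package."""


class TFDenoiseError(Exception):
    """Base class for all package errors."""


class InvalidInputError(TFDenoiseError, ValueError):
    """A signal or matrix violates its invariants (non-finite values, bad shape...)."""


class InvalidParameterError(TFDenoiseError, ValueError):
    """A configuration value is outside its admissible range."""


class InsufficientExtremaError(TFDenoiseError, RuntimeError):
    """Too few (or degenerate) extrema to build an envelope surface.

    Raised by envelope construction; callers stop sifting when they see it.
    """


class UndefinedMetricError(TFDenoiseError, ValueError):
    """The requested metric is undefined for this (reference, estimate) pair."""
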