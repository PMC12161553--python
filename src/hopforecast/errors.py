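"""Exception types shared across the package."""


class HopforecastError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(HopforecastError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class FormatError(HopforecastError, ValueError):
    """A file does not match the expected delimited-text layout."""


class ScoreValidationError(HopforecastError, ValueError):
    """An indicator score lies outside its allowed level set."""


class FittingError(HopforecastError, RuntimeError):
    """The training data cannot support a fit (e.g. a class is missing)."""


class DegenerateInputError(HopforecastError, ValueError):
    """An input is degenerate for the requested statistic (e.g. zero variance)."""
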