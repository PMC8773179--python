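"""Exception hierarchy shared across the pipeline stages."""


class ScreenError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(ScreenError, ValueError):
    """Invalid parameter combination (capacity, overlapping effect sets, ...)."""


class LibraryParseError(ScreenError, ValueError):
    """Malformed or inconsistent siRNA library table."""


class LibraryLookupError(ScreenError, KeyError):
    """A gene required by a layout cannot be resolved to a library source well."""


class PlateScoringError(ScreenError, ValueError):
    """A plate cannot be scored (e.g. fewer than two usable NT wells)."""
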