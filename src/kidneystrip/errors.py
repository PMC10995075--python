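"""Exception hierarchy shared across the package.

Every error raised by kidneystrip derives from :class:`KidneyStripError` so
callers (and the CLI exit-code mapping) can distinguish configuration
problems, invalid data, and model-fitting failures.
"""


class KidneyStripError(Exception):
    """Base class for all kidneystrip errors."""


class ConfigurationError(KidneyStripError, ValueError):
    """Invalid configuration: bad ranges, unknown names, malformed specs."""


class DomainError(KidneyStripError, ValueError):
    """Input value outside the mathematical domain of an operation."""


class SizeError(KidneyStripError, ValueError):
    """Image or array dimensions incompatible with the requested operation."""


class DegenerateInputError(KidneyStripError, ValueError):
    """Input is structurally valid but degenerate (e.g. fully masked image)."""


class FitError(KidneyStripError, RuntimeError):
    """Model fitting cannot proceed (e.g. an empty partition bin)."""


class StratificationError(KidneyStripError, ValueError):
    """Cross-validation stratification is impossible for the given data."""
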