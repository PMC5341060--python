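"""Exception hierarchy.

All package-specific failures derive from :class:`VoiceLawsError` so callers
can catch one base class; the CLI maps subclasses onto exit codes
(input error -> 2, degenerate data -> 3).
"""


class VoiceLawsError(Exception):
    """Base class for all voicelaws errors."""


class InputError(VoiceLawsError):
    """Unreadable, truncated or malformed input data."""


class UnsupportedFormatError(InputError):
    """File encoding the reader does not handle."""


class ParameterError(VoiceLawsError, ValueError):
    """Out-of-domain parameter value."""


class DegenerateDataError(VoiceLawsError):
    """Data that cannot support the requested statistic (constant series,
    empty token sequence, single-point distribution...)."""


class InsufficientDataError(DegenerateDataError):
    """Too few samples above the fitting cutoff."""
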