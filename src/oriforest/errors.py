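"""Exception hierarchy shared across the package.

All data-driven failures derive from :class:`InputDataError` so the CLI can
map them onto a dedicated exit code, distinct from configuration errors
(bad flags, out-of-range parameters) and genuine internal faults.
"""


class OriForestError(Exception):
    """Base class for every error raised by this package."""


class InputDataError(OriForestError, ValueError):
    """A problem with user-supplied data (files, sequences, labels)."""


class AlphabetError(InputDataError):
    """A sequence contains a character outside the {A, C, G, T} alphabet."""


class EmptyInputError(InputDataError):
    """An operation received no records where at least one is required."""


class LengthMismatchError(InputDataError):
    """Sequences do not share the single common length the operation needs."""


class ContaminationError(InputDataError):
    """The same sequence appears in both the positive and negative class."""


class ConfigError(OriForestError, ValueError):
    """An invalid parameter value (threshold, fold count, window, ...)."""
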