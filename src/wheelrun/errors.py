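"""Exception hierarchy.

Everything raised deliberately by this package derives from :class:`WheelrunError`
so callers (and the CLI) can separate data/usage problems from genuine bugs.
"""


class WheelrunError(Exception):
    """Base class for all wheelrun errors."""


class SortOrderError(WheelrunError):
    """An event stream was not sorted by time."""


class ConfigError(WheelrunError):
    """Invalid configuration value or inconsistent config combination."""


class ParameterError(WheelrunError):
    """Invalid simulator parameter (rate < 0, proportion outside [0, 1], ...)."""


class CapacityError(WheelrunError):
    """More animals requested than logger channels available."""


class LogParseError(WheelrunError):
    """A logger CSV row could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


class LogDialectError(WheelrunError):
    """A logger CSV header does not match the expected dialect."""


class InsufficientDataError(WheelrunError):
    """Not enough recorded reset times to impute the missing ones."""


class ConsistencyError(WheelrunError):
    """Logically inconsistent inputs (e.g. overlapping logger sessions)."""


class DegenerateInputError(WheelrunError):
    """An operation received input with no usable signal (e.g. all-zero minutes)."""


class ValidationError(WheelrunError):
    """A data record failed an internal consistency check."""
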