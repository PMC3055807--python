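"""Exception hierarchy for the simulator.

Everything raised deliberately by eposim derives from :class:`EposimError`
so callers can catch simulator errors without masking programming bugs.
"""


class EposimError(Exception):
    """Base class for all eposim errors."""


class ConfigurationError(EposimError, ValueError):
    """Model constants or session configuration violate an invariant."""


class DomainError(EposimError, ValueError):
    """An argument is outside the physical/mathematical domain of an operation."""


class SchedulingError(EposimError, ValueError):
    """A dose event is dated to a day other than the current simulation day."""


class UndefinedStateError(EposimError, ValueError):
    """A read-out was requested on a state for which it is undefined (e.g. empty)."""


class InsufficientDataError(EposimError, ValueError):
    """A statistic needs more values than the series provides."""


class PolicyError(EposimError, ValueError):
    """A prescriber policy produced an unusable dose or lacked observations."""


class SessionAbortedError(EposimError, RuntimeError):
    """An interactive session ended before week 32.

    Carries the rows logged so far in ``partial_rows`` so a truncated log
    can still be written for inspection.
    """

    def __init__(self, message, partial_rows=None):
        super().__init__(message)
        self.partial_rows = partial_rows or []


class CalibrationError(EposimError, RuntimeError):
    """Dose-response calibration failed to converge or verify."""


class SessionCsvError(EposimError, ValueError):
    """A session log file is malformed."""
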