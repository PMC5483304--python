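"""Exception hierarchy for mpalss.

All errors derive from :class:`MpalssError` so callers can catch the whole
family; the concrete subclasses mirror the distinct failure modes of the
analysis (bad profiles, degenerate designs, undefined tests).
"""


class MpalssError(ValueError):
    """Base class for all package-specific errors."""


class InvalidProfileError(MpalssError):
    """A concentration-time profile violates a structural invariant."""


class IncompleteIntervalError(MpalssError):
    """AUC(0-12) requested on a profile not spanning [0, 12] h.

    No extrapolation is performed: the trapezoidal AUC is only defined when
    both the pre-dose (0 h) and end-of-interval (12 h) samples were observed.
    """


class DomainError(MpalssError):
    """A scalar argument is outside its mathematical domain (e.g. AUC <= 0)."""


class ProfileIOError(MpalssError):
    """A profile CSV is malformed; the message names the offending line(s)."""


class CollinearityError(MpalssError):
    """The regression design matrix is rank deficient.

    ``column`` holds the sampling time (h) of the first predictor found to be
    linearly dependent on the others (or constant).
    """

    def __init__(self, message: str, column: float | None = None):
        super().__init__(message)
        self.column = column


class InsufficientDataError(MpalssError):
    """Too few profiles to fit or cross-validate an equation."""


class MissingSampleError(MpalssError):
    """A profile lacks a concentration at a required sampling time.

    ``time_h`` holds the missing time.
    """

    def __init__(self, message: str, time_h: float | None = None):
        super().__init__(message)
        self.time_h = time_h


class UndefinedTestError(MpalssError):
    """A statistical test is undefined on the given data (e.g. all-zero
    paired differences in the signed-rank test)."""


class DegenerateInputError(MpalssError):
    """Input with zero variance (or similar) where spread is required."""
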