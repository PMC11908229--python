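"""Typed exceptions. Each names the invariant it reports."""


class LickwaveError(Exception):
    """Base class for all package errors."""


class SessionFormatError(LickwaveError):
    """A stored session violates the format contract."""


class MissingChannelError(SessionFormatError):
    """A required dataset/column (f465, f405, licks) is absent."""


class LengthMismatchError(SessionFormatError):
    """f465 and f405 (or table columns) have unequal lengths."""


class NonMonotonicTimeError(SessionFormatError):
    """The time base of a stored signal is not strictly increasing."""


class DegenerateControlError(LickwaveError):
    """The 405 nm control channel is constant; the control fit is undefined."""


class NonPositiveFittedError(LickwaveError):
    """The fitted control trace is <= 0 somewhere; the dF/F ratio is undefined."""

    def __init__(self, index: int):
        self.index = int(index)
        super().__init__(
            f"fitted control channel is <= 0 at sample {self.index}; "
            "cannot form (F465 - fit)/fit"
        )


class GridMismatchError(LickwaveError):
    """Two peri-event results do not share the same bin grid."""


class SessionTooShortError(LickwaveError):
    """Requested lick-train structure cannot fit in the session length."""


class EmptyInputError(LickwaveError):
    """An operation that needs at least one element received none."""


class ExcludedSnipError(LickwaveError):
    """An operation defined only for included snips received an excluded one."""
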