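"""Exception hierarchy shared across the package.

All errors derive from :class:`EmdEegError` so callers can catch the
package's failures with a single clause while still distinguishing the
common cases (bad input, degenerate signals, missing channels, malformed
files).
"""


class EmdEegError(Exception):
    """Base class for all errors raised by emdeeg."""


class InvalidInputError(EmdEegError, ValueError):
    """Input violates a documented precondition (shape, range, finiteness)."""


class NotEnoughExtremaError(EmdEegError):
    """Too few extrema to build spline envelopes; signal behaves as a residual."""


class DegenerateSignalError(EmdEegError):
    """Signal carries no usable information (all zero, zero variance)."""


class MissingChannelError(EmdEegError, KeyError):
    """A requested channel label is absent from the recording."""


class FormatError(EmdEegError):
    """An on-disk dataset does not match its documented layout."""
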