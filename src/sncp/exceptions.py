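"""Exception hierarchy for sncp.

All package-raised errors derive from :class:`SNCPError` so callers can
catch them with a single ``except`` clause; the subclasses distinguish
bad user input from internal contract violations and from inputs that are
formally valid but make a statistic undefined.
"""


class SNCPError(Exception):
    """Base class for all sncp errors."""


class InvalidInputError(SNCPError, ValueError):
    """User-supplied data or configuration is unusable (non-finite values,
    series too short, malformed file, ...)."""


class ContractError(SNCPError, ValueError):
    """An internal pre-condition was violated (index out of range,
    dimension mismatch between parameters and order, ...)."""


class DegenerateInputError(SNCPError, ValueError):
    """The input is formally valid but a required normalizer is zero,
    so the statistic is undefined (e.g. constant residuals)."""
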