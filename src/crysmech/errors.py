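"""Exception hierarchy.

Every error raised by the package derives from :class:`CrysmechError`, so
callers can catch domain failures without masking programming errors.
"""


class CrysmechError(Exception):
    """Base class for all package errors."""


class InputError(CrysmechError, ValueError):
    """Invalid argument value (negative count, empty trace, ...)."""


class TopologyError(CrysmechError):
    """Construct topology unsupported by the requested operation."""


class StateError(CrysmechError):
    """Operation requires state the object does not carry (e.g. no swap motif)."""


class ConfigError(CrysmechError):
    """Inconsistent or unsafe configuration (overlapping class windows, coarse dt)."""


class CalibrationError(CrysmechError):
    """Bell-parameter calibration found no solution within bounds."""


class FitError(CrysmechError):
    """Worm-like-chain segment fit is underdetermined or degenerate."""


class FilterError(CrysmechError):
    """Kalman filter diverged (non-finite or overflowing variance)."""


class InconsistencyError(CrysmechError):
    """Measured ledger incompatible with the swap model (negative loop length)."""


class EstimationError(CrysmechError):
    """Statistical estimate requested from an empty or unusable sample."""
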