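"""Exception and warning types shared across the package."""


class RollGaitError(Exception):
    """Base class for all rollgait errors."""


class InvalidInputError(RollGaitError, ValueError):
    """An input violates a precondition (shape, length, norm, emptiness)."""


class DegenerateInputError(RollGaitError, ValueError):
    """An input is formally valid but carries no usable signal
    (e.g. zero variance where a correlation is required)."""


class InvalidStateError(RollGaitError, RuntimeError):
    """An operation was applied to an object in the wrong state
    (e.g. zeroing an already-zeroed series)."""


class ConfigError(RollGaitError, ValueError):
    """A configuration value is missing or out of range."""


class GimbalLockWarning(UserWarning):
    """Pitch is numerically at ±90°; roll returned from a stabilized form."""


class ZeroVarianceTTestWarning(UserWarning):
    """Paired differences have zero variance; p-value set by convention."""
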