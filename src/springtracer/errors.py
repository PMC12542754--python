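"""Exception hierarchy.

The CLI maps these onto exit codes: validation/usage/data problems exit 1,
failures inside a computation (non-convergence, degenerate denominators)
exit 2.
"""


class SpringTracerError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SpringTracerError):
    """A configuration object or calibration is unusable (e.g. empty quench curve)."""


class DataError(SpringTracerError):
    """Input data violate an invariant (negative volume, efficiency <= 0, ...)."""


class UsageError(SpringTracerError):
    """An operation was called with incompatible arguments (e.g. substrate mismatch)."""


class ComputationError(SpringTracerError):
    """A computation could not be completed (zero denominator, non-convergence)."""
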