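"""Exception hierarchy shared across the package."""


class RapError(Exception):
    """Base class for all package errors."""


class ValidationError(RapError, ValueError):
    """An input, parameter or configuration field is out of its valid range."""


class SimulationError(RapError, RuntimeError):
    """The virtual-patient integration produced a non-finite state."""


class DataError(RapError, ValueError):
    """An on-disk event log violates the expected schema or cadence."""


class UndefinedMetricError(RapError, ZeroDivisionError):
    """A metric was requested on an empty denominator (no meals / no alerts)."""
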