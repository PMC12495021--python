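"""Exception hierarchy shared across the package."""


class SpikegraphError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(SpikegraphError, ValueError):
    """A function argument is outside its documented range."""


class FormatError(SpikegraphError, ValueError):
    """A text table could not be parsed."""


class ScheduleError(SpikegraphError, ValueError):
    """A stimulus schedule violates its invariants (e.g. overlapping trials)."""


class EstimationError(SpikegraphError, RuntimeError):
    """A statistical fit cannot be carried out on the given data."""


class SimulationError(SpikegraphError, RuntimeError):
    """A simulation cannot proceed (e.g. unbounded intensity)."""


class ConfigError(SpikegraphError, ValueError):
    """A run configuration failed validation; carries an itemized message."""
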