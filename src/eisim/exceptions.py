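class EisimError(Exception):
    """Base class for package errors."""


class ParameterError(EisimError, ValueError):
    """Invalid configuration or argument value."""


class SimulationError(EisimError, RuntimeError):
    """Numerical failure during network integration."""
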