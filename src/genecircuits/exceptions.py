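"""Package-specific exception types."""


class GeneCircuitError(Exception):
    """Base class for all errors raised by this package."""


class IntegrationError(GeneCircuitError):
    """The ODE solver failed to advance the solution."""


class NormalizationError(GeneCircuitError):
    """A gene could not be max-normalized (e.g. all-zero expression)."""


class ConfigurationError(GeneCircuitError):
    """An infeasible or inconsistent configuration was supplied."""


class CalibrationError(GeneCircuitError):
    """A perturbation could not be calibrated to the requested fold change."""
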