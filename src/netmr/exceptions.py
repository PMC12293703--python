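"""Exception hierarchy for the netmr pipeline."""


class NetmrError(Exception):
    """Base class for all netmr errors."""


class SchemaError(NetmrError):
    """A mandatory column is missing from a summary-statistics file."""


class EmptyInputError(NetmrError):
    """No valid rows survived validation."""


class ValidationError(NetmrError):
    """A value violates a data-model invariant (e.g. r2 outside [0, 1])."""


class HarmonizationError(NetmrError):
    """Harmonization retained zero usable variants."""


class EstimationError(NetmrError):
    """A causal estimate cannot be formed (degenerate regression, zero divisor)."""


class InsufficientInstrumentsError(EstimationError):
    """Fewer instruments than the method requires."""


class ConfigurationError(NetmrError):
    """Inconsistent or invalid run configuration."""
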