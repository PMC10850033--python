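"""Exception types shared across the pipeline stages."""


class SurgDelayError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SurgDelayError, ValueError):
    """A run or generator configuration is invalid or incomplete."""


class DataValidationError(SurgDelayError, ValueError):
    """An input table violates the schema or invariants a stage relies on."""
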