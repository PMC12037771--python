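"""Exception hierarchy used across the pipeline."""


class VttmlError(Exception):
    """Base class for all package errors."""


class ConfigurationError(VttmlError):
    """Invalid configuration (cohort spec, pipeline config, run config)."""


class ValidationError(VttmlError):
    """Invalid data passed to an operation (negative lengths, missing classes...)."""
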