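"""Exception types shared across the pipeline."""


class PipelineError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(PipelineError, ValueError):
    """An invalid simulation or analysis configuration value; names the field."""


class FormatError(PipelineError, ValueError):
    """A malformed input file; message carries the offending line / cell."""
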