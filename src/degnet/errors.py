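"""Shared exception types."""


class DegnetError(Exception):
    """Base class for all package errors."""


class ParseError(DegnetError, ValueError):
    """A file could not be parsed; the message names the offending location."""


class ValidationError(DegnetError, ValueError):
    """An input violates a documented invariant."""


class ConfigError(DegnetError, ValueError):
    """A configuration value is inconsistent or out of range."""


class PipelineError(DegnetError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")
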