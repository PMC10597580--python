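"""Exception hierarchy shared across the package.

``ConfigError`` and ``ParseError`` map to CLI exit code 1 (validation);
everything else bubbles up as a runtime failure (exit code 2).
"""


class FtxError(Exception):
    """Base class for package errors."""


class ConfigError(FtxError, ValueError):
    """Invalid configuration or parameter values."""


class DomainError(FtxError, ValueError):
    """Input violates a mathematical precondition (e.g. SD <= 0)."""


class ParseError(FtxError, ValueError):
    """Malformed input file; message carries the offending location."""


class PipelineError(FtxError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
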