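"""Exception hierarchy shared across the pipeline."""


class CircKitError(Exception):
    """Base class for all circkit errors."""


class ConfigurationError(CircKitError):
    """A user-supplied option or config value is invalid or inconsistent."""


class ParseError(CircKitError):
    """A file could not be parsed.

    Carries the path and (1-based) line number when known.
    """

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class DomainError(CircKitError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class PipelineError(CircKitError):
    """A pipeline stage failed; names the stage and offending input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
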