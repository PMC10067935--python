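"""Shared exception types."""


class ConfigError(ValueError):
    """An invalid generator or pipeline configuration."""


class ParseError(ValueError):
    """A malformed input file; carries the offending line number."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        where = ""
        if path is not None:
            where = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + where)


class IntegrityError(ValueError):
    """A referential-integrity violation across input tables."""


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; names the stage for the operator."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
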