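"""Exception hierarchy for the pathfuse pipeline.

Every stage raises a subclass of :class:`PathfuseError` so the CLI can abort
with a stage-named message and a non-zero exit code.
"""


class PathfuseError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(PathfuseError):
    """Invalid simulation or pipeline configuration."""


class ParseError(PathfuseError):
    """Malformed input file; carries the offending path/line when known."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        elif line is not None:
            loc += f" [line {line}]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class EmptyAfterQCError(PathfuseError):
    """No SNP survived quality control."""


class UndefinedStatisticError(PathfuseError):
    """A test statistic is undefined for the given counts (zero variance)."""


class MonomorphicSNPError(PathfuseError):
    """r² is undefined because a SNP is monomorphic in the reference panel."""


class ConsistencyError(PathfuseError):
    """Cross-references between artifacts do not line up (missing ids etc.)."""


class PipelineStageError(PathfuseError):
    """Wraps any stage failure with the stage name for CLI reporting."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
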