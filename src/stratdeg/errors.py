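"""Exception hierarchy shared across the pipeline stages."""


class StratdegError(Exception):
    """Base class for all package errors."""


class ConfigError(StratdegError):
    """Invalid or incomplete run configuration."""


class ParseError(StratdegError):
    """Unrecoverable input-parsing failure (e.g. empty stream)."""


class ValidationError(StratdegError):
    """An input violates a documented precondition or invariant."""


class UndefinedResultError(StratdegError):
    """A statistic is undefined for the given table (degenerate margins)."""


class InfeasibleParadoxError(StratdegError):
    """The requested Simpson-paradox construction cannot exist."""


class StageError(StratdegError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
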