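"""Exception hierarchy shared across the engine."""


class EmflowError(Exception):
    """Base class for all engine errors."""


class StarParseError(EmflowError):
    """Malformed STAR text; carries a 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(EmflowError):
    """A request violates a typed constraint (I/O types, alias syntax, parameter domain)."""


class RegistryLookupError(EmflowError, KeyError):
    """Unknown node-type or job-type identifier."""


class PipelineError(EmflowError):
    """Structural pipeline problem: unknown ids, corrupt persisted state, cycles."""
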