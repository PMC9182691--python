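"""Exception hierarchy for the mirfeat pipeline."""


class MirfeatError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MirfeatError):
    """A configuration value is invalid or a required input is missing."""


class ParseError(MirfeatError):
    """A flat file could not be parsed.

    Carries the 1-based line number where parsing failed, when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(MirfeatError):
    """Input data violates a documented precondition."""
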