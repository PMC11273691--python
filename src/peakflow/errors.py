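"""Exception hierarchy shared across the package."""


class PeakflowError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PeakflowError, ValueError):
    """An argument or data structure violates a documented precondition."""


class FormatError(ValidationError):
    """A text input file violates its format contract.

    Carries the offending path and 1-based line number when known, so the
    user can jump straight to the broken record.
    """

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class ConfigError(ValidationError):
    """An initialization file is malformed or references unknown keys."""
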