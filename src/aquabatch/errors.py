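"""Exception types shared across the package."""

from __future__ import annotations


class AquabatchError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(AquabatchError, ValueError):
    """A parameter, field or precondition is invalid. The message names the field."""


class ParseError(AquabatchError, ValueError):
    """An input file does not conform to the output dialect.

    Carries the offending path and, where known, the 1-based line number.
    """

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f" [{path}"
            if line is not None:
                loc += f":{line}"
            loc += "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class AmbiguityError(AquabatchError, ValueError):
    """A run prefix matches both GUI-only and plug-in-only file families."""
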