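"""Exception hierarchy shared across the package."""


class PolKineticsError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(PolKineticsError):
    """A configuration value violates its documented constraints."""


class InputError(PolKineticsError):
    """An input table or track violates its contract (negative values, bad shape...)."""


class ParseError(InputError):
    """A text track or table could not be parsed; carries file and line context."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class AnnotationMismatchError(InputError):
    """A selected isoform has no known transcript structure."""


class FitError(PolKineticsError):
    """A model fit could not be performed on the given observations."""


class StageError(PolKineticsError):
    """A pipeline stage was invoked before its upstream artifacts exist."""

    def __init__(self, message: str, missing_stage: str | None = None):
        super().__init__(message)
        self.missing_stage = missing_stage
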