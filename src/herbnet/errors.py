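"""Exception types shared across the pipeline."""


class HerbnetError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(HerbnetError):
    """A configuration value is invalid; the message names the offending field."""


class ValidationError(HerbnetError):
    """Input data violates an invariant of the claims data model."""


class ParseError(HerbnetError):
    """A claims file could not be parsed.

    Carries enough context (file, line, column) to locate the offending row.
    """

    def __init__(self, message: str, *, file: str | None = None,
                 line: int | None = None, column: str | None = None):
        self.file = file
        self.line = line
        self.column = column
        loc = ""
        if file is not None:
            loc = f"{file}"
            if line is not None:
                loc += f":{line}"
            if column is not None:
                loc += f" (column {column})"
            loc = f" [{loc}]"
        super().__init__(message + loc)
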