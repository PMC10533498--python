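"""Exception and warning types shared across the package."""


class FateScreenError(Exception):
    """Base class for all labeled errors raised by fatescreen."""


class ParseError(FateScreenError):
    """A text input (GCT/GMT/TSV) is malformed.

    Carries the offending path and 1-based line number when known.
    """

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        super().__init__(message + loc)


class ValidationError(FateScreenError):
    """An input violates a documented precondition."""


class MissingLabelError(ValidationError):
    """A requested condition/cluster label is absent from the data."""


class EmptyOverlapError(ValidationError):
    """A gene set does not overlap the ranked list / gene universe enough."""


class FateScreenWarning(UserWarning):
    """Non-fatal data issues: dropped genes, skipped profiles, empty sides."""
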