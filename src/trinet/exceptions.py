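"""Exception hierarchy for trinet."""


class TrinetError(Exception):
    """Base class for all trinet errors."""


class ValidationError(TrinetError, ValueError):
    """An input object violates a documented invariant."""


class ParseError(TrinetError, ValueError):
    """A file could not be parsed.

    Carries enough location information (``row``, ``column``, ``line``)
    to point the user at the offending cell or line.
    """

    def __init__(self, message, *, row=None, column=None, line=None):
        super().__init__(message)
        self.row = row
        self.column = column
        self.line = line
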