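"""Exception hierarchy shared across the pipeline.

Every error raised on purpose derives from :class:`PhenoconcordError` so
callers (and the CLI) can separate pipeline failures from genuine bugs.
"""


class PhenoconcordError(Exception):
    """Base class for all deliberate pipeline errors."""


class FormatError(PhenoconcordError):
    """A file does not conform to its declared dialect (missing column, short GMT line...)."""


class EmptyInputError(PhenoconcordError):
    """A parse retained zero usable rows."""


class RowParseError(FormatError):
    """A single row could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class DataError(PhenoconcordError):
    """Values present are unusable for the requested operation (e.g. missing q-values)."""


class DomainError(PhenoconcordError):
    """A numeric argument is outside its mathematical domain."""


class ConfigError(PhenoconcordError):
    """A run or simulation configuration is inconsistent."""


class AlignmentError(PhenoconcordError):
    """Two keyed vectors that must share keys do not; message lists the difference."""
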