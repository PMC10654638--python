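"""Exception hierarchy shared across the package."""


class PvSignalsError(Exception):
    """Base class for all package-specific errors."""


class InvalidTermError(PvSignalsError):
    """A term is empty (or whitespace-only) after normalization."""


class LexiconError(PvSignalsError):
    """A drug lexicon is inconsistent, or a canonical name is unknown."""


class StoreStateError(PvSignalsError):
    """An operation required a deduplicated store but got a raw one."""


class ParseError(PvSignalsError):
    """A report file row could not be parsed (carries the line number)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConfigError(PvSignalsError):
    """A simulation or grouping configuration failed validation."""


class UnsolvableError(PvSignalsError):
    """Table reconstruction target lies at or beyond the feasible asymptote."""

    def __init__(self, message: str, asymptote: float | None = None):
        self.asymptote = asymptote
        super().__init__(message)
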