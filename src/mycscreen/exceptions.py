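"""Exception hierarchy for the screening pipeline."""


class MycScreenError(Exception):
    """Base class for all package errors."""


class ParseError(MycScreenError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(MycScreenError):
    """An in-memory object violates one of its invariants."""


class EmptyScreenError(MycScreenError):
    """A filter or restriction removed every signature (or every DEG)."""


class UndefinedScoreError(MycScreenError):
    """A score is requested whose denominator or null is degenerate."""
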