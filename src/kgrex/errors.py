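"""Exception types shared across kgrex modules."""


class KgrexError(ValueError):
    """Base class for kgrex errors."""


class ParseError(KgrexError):
    """A file could not be parsed (malformed JSON line, bad column count, ...)."""


class ValidationError(KgrexError):
    """Parsed content violates a schema or domain invariant."""
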