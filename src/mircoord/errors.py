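"""Exception types shared across the package."""


class MircoordError(Exception):
    """Base class for package errors."""


class ParseError(MircoordError, ValueError):
    """A file could not be parsed; message carries the offending line number."""


class ValidationError(MircoordError, ValueError):
    """Input violated an invariant (duplicate ids, dangling edges, ...)."""
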