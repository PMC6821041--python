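"""Typed errors raised throughout the package.

Every malformed input raises one of these; nothing is silently truncated
or coerced.
"""


class LowbiomError(Exception):
    """Base class for all package errors."""


class FormatError(LowbiomError, ValueError):
    """A file does not conform to the expected on-disk dialect."""


class ValidationError(LowbiomError, ValueError):
    """Structurally parseable input that violates a domain invariant."""


class AnalysisError(LowbiomError, RuntimeError):
    """An analysis was requested on data that cannot support it."""
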