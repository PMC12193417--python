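"""Typed exceptions raised throughout the package.

Every malformed input raises :class:`ValidationError` (or a subclass) with a
message naming the offending row/column/sample; nothing is silently coerced.
"""


class EchinodivError(Exception):
    """Base class for all package errors."""


class ValidationError(EchinodivError, ValueError):
    """An input file or in-memory object violates its contract."""


class SaturationError(EchinodivError, ValueError):
    """A K2P distance is undefined (logarithm argument <= 0)."""
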