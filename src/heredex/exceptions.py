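"""Exception hierarchy.

Every error raised by heredex derives from :class:`HeredexError`, so callers
(and the CLI) can catch one type. All of them are also ``ValueError`` so the
package plays nicely with generic validation code.
"""


class HeredexError(ValueError):
    """Base class for all heredex errors."""


class ConfigError(HeredexError):
    """A configuration field is invalid; the message names the field."""


class DomainError(HeredexError):
    """A numeric argument lies outside its mathematical domain."""


class ShapeError(HeredexError):
    """Structurally inconsistent arrays (length mismatch, empty input)."""


class UsageError(HeredexError):
    """An unknown option value, e.g. an unrecognised relationship tag."""


class UndefinedCorrelationError(HeredexError):
    """A correlation is requested where it is mathematically undefined
    (constant array, zero margin in a 2x2 table)."""
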