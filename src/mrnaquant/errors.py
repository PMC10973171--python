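"""Exception hierarchy.

All package errors derive from :class:`MrnaQuantError`; user-input problems
(bad config, bad sequence, bad measurement) derive from
:class:`ValidationError` so front ends can map them to a distinct exit code.
"""


class MrnaQuantError(Exception):
    """Base class for all package errors."""


class ValidationError(MrnaQuantError, ValueError):
    """Invalid user input: config, sequence, scheme, or measurement."""


class ConfigError(ValidationError):
    """A registry config file failed to parse or violated an invariant."""


class SequenceError(ValidationError):
    """A sequence contains characters outside the accepted alphabet."""


class UnknownCodeError(MrnaQuantError, KeyError):
    """A residue or cap code is not present in the active registry."""

    def __init__(self, code: str) -> None:
        super().__init__(code)
        self.code = code

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message plain
        return f"unknown nucleoside or cap code: {self.code!r}"


class UndefinedRatioError(MrnaQuantError, ZeroDivisionError):
    """A hypochromicity ratio is undefined (zero reference absorption)."""


class DegenerateDesignError(ValidationError):
    """A regression design has no spread in the predictor."""
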