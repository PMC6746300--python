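"""Exception hierarchy shared across the package."""


class ChearrayError(Exception):
    """Base class for all package errors."""


class ValidationError(ChearrayError, ValueError):
    """Invalid parameter or malformed input."""


class RangeError(ChearrayError, LookupError):
    """Requested object not containable in / resolvable from the input."""


class ConfigurationError(ChearrayError, KeyError):
    """Missing template, anchor, or other required configuration entry."""


class NumericError(ChearrayError, ArithmeticError):
    """Non-finite values encountered during a numeric procedure."""
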