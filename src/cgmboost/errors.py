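"""Exception hierarchy for cgmboost."""


class CGMBoostError(Exception):
    """Base class for all cgmboost errors."""


class TraceValidationError(CGMBoostError):
    """A glucose trace violates the regular-grid or physiological invariants."""


class ParseError(CGMBoostError):
    """An input file could not be parsed into valid records."""


class ConfigurationError(CGMBoostError):
    """A threshold, meal-schedule or simulation configuration is invalid."""


class DataError(CGMBoostError):
    """A dataset violates the preconditions of a training or evaluation routine."""
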