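"""Exception hierarchy shared across the package."""


class PrizeForestError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PrizeForestError):
    """A configuration value is invalid; the message names the field."""


class InputError(PrizeForestError):
    """An input value or file violates a precondition."""


class ParseError(InputError):
    """A tabular input could not be parsed; carries a line number when known."""


class EstimationError(PrizeForestError):
    """A statistical estimate cannot be computed from the data given."""


class UnsupportedDesignError(PrizeForestError):
    """The experimental design is outside the two-sample scope."""


class SizeGuardError(PrizeForestError):
    """An exact algorithm was asked to run on an instance beyond its guard."""


class TuningFailedError(PrizeForestError):
    """No admissible parameter combination was found on the tuning grid."""
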