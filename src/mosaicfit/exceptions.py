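"""Exception hierarchy for mosaicfit."""


class MosaicfitError(Exception):
    """Base class for all mosaicfit errors."""


class DomainError(MosaicfitError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class ConfigurationError(MosaicfitError, ValueError):
    """A configuration object or option set is invalid."""


class ValidationError(MosaicfitError, ValueError):
    """Input records violate the schema or an operation's preconditions."""


class InsufficientDataError(MosaicfitError, ValueError):
    """Too few observations to run the requested estimation."""


class NoPlateauError(MosaicfitError, RuntimeError):
    """No density plateau found when proposing mixture split points."""
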