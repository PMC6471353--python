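"""Exception types shared across the package."""


class PlatewormError(Exception):
    """Base class for domain errors raised by this package."""


class PlacementError(PlatewormError):
    """A synthetic object could not be placed under its geometric constraints."""


class ConfigurationError(PlatewormError):
    """A model or command was used with a mismatched or invalid configuration."""


class TrainingError(PlatewormError):
    """The training data cannot produce a valid classifier."""
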