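"""Exception hierarchy."""


class LarvaForageError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(LarvaForageError):
    """Non-positive lengths, patches poking out of the arena, and the like."""


class InvalidArgumentError(LarvaForageError, ValueError):
    pass


class PackingFailureError(LarvaForageError):
    """Random patch placement exhausted its rejection-sampling budget."""


class OutOfBoundsError(LarvaForageError):
    pass


class InvalidLayoutError(LarvaForageError):
    pass


class DataQualityError(LarvaForageError):
    """Non-finite or otherwise unusable tracker data."""


class InsufficientDataError(LarvaForageError):
    pass


class ConfigurationError(LarvaForageError):
    pass
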