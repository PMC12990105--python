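"""Exception hierarchy shared across the package."""


class EpathError(Exception):
    """Base class for all epathcv errors."""


class ParseError(EpathError):
    """A file could not be parsed under its declared format."""


class ValidationError(EpathError):
    """An input violates a documented precondition."""


class GeometryError(EpathError):
    """A geometric operation is ill-posed for the given coordinates."""
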