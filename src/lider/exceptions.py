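"""Exception hierarchy shared across the package."""


class LiderError(Exception):
    """Base class for all package-specific errors."""


class FormatError(LiderError):
    """A file does not conform to the expected on-disk layout."""


class ParseError(LiderError):
    """A value inside an otherwise well-formed file could not be parsed."""


class DimensionError(LiderError):
    """Array/file dimensions are inconsistent with each other or a model."""


class DuplicateKeyError(LiderError):
    """An identifier that must be unique appears more than once."""


class AlignmentError(LiderError):
    """Two datasets share no genes and cannot be placed on a common axis."""


class ParameterError(LiderError):
    """A configuration value is outside its legal range."""


class DataError(LiderError):
    """Input data violates a numeric precondition (e.g. NaN values)."""


class DivergenceError(LiderError):
    """Training produced a non-finite loss; reduce the learning rate."""


class LabelError(LiderError):
    """A label is outside the known class vocabulary."""
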