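"""Exception hierarchy used across the package."""


class SpatialABMError(Exception):
    """Base class for all package errors."""


class FormatError(SpatialABMError, ValueError):
    """A file or container is structurally not what the reader expects."""


class ParseError(SpatialABMError, ValueError):
    """A value inside an otherwise well-formed file cannot be parsed."""


class ValidationError(SpatialABMError, ValueError):
    """An in-memory object violates a documented invariant."""


class ConfigError(SpatialABMError, ValueError):
    """A simulation or experiment configuration is internally inconsistent."""
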