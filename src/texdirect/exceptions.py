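"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class DimensionError(ValidationError):
    """Raised when an image is too small for the requested operation."""
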