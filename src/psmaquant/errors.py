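"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Input data violate a documented invariant (negative SUV, bad table row, ...)."""


class DimensionalityError(ValidationError):
    """An image does not have exactly three spatial axes."""


class GeometryMismatchError(ValidationError):
    """Two grids that must share shape/spacing do not."""


class DegenerateDataError(ValueError):
    """A statistical routine received input with no usable information."""
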