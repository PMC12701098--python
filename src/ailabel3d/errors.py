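"""Exception types shared across the package."""


class DimensionalityError(ValueError):
    """An image has the wrong rank (e.g. a 2D or 4D NIfTI where 3D is required)."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but carries no usable signal
    (constant volume, empty mask, empty region, ...)."""


class NumericError(ValueError):
    """Non-finite values where finite ones are required."""


class IncompleteDataError(ValueError):
    """A record that must be complete (e.g. a blind-trial sheet) has gaps."""
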