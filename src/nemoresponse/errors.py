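"""Exception and warning types shared across the package."""


class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition."""


class DataError(ValueError):
    """Input data violate an invariant (e.g. non-positive fluorescence)."""


class ConfigError(ValueError):
    """A run configuration failed validation."""


class DegenerateNullWarning(UserWarning):
    """The fitted air-control null has zero standard deviation.

    Every nonzero response then classifies as non-silent; results should be
    interpreted with care (usually a sign that the air controls are identical
    copies or noise-free simulations).
    """
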