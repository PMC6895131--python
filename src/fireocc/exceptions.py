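"""Exception types shared across the package."""


class InvalidArgumentError(ValueError):
    """An argument is outside its documented domain."""


class InfeasibleDesignError(RuntimeError):
    """A survey design cannot be realized (e.g. site spacing impossible)."""


class EmptyBufferError(ValueError):
    """A buffer intersects no raster cells."""


class CollinearityError(ValueError):
    """A regression design matrix is rank deficient."""


class DegenerateCovariateError(ValueError):
    """A covariate is constant (or too short) and cannot be standardized."""


class ShapeError(ValueError):
    """Arrays that must agree in shape or indexing do not."""


class DataValidationError(ValueError):
    """Input data contain NaN/invalid values or violate basic contracts."""
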