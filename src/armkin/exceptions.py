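"""Exception types shared across the package.

Validation failures raise :class:`ValidationError` subclasses (a CLI maps
these to exit code 2); numerical failures raise
:class:`NumericalError` subclasses (exit code 3).
"""


class ValidationError(ValueError):
    """Invalid input data or configuration."""


class DegenerateCurveError(ValidationError):
    """Curve has too few distinct points (or zero total arclength)."""


class DegenerateTriangleError(ValidationError):
    """Coincident points make a circumcircle/triangle undefined."""


class ShapeError(ValidationError):
    """Mismatched array shapes or grids."""


class NoBendError(ValidationError):
    """Curvature profile everywhere below the bend-detection floor."""


class NumericalError(RuntimeError):
    """A numerical routine failed to produce a usable result."""
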