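"""Exception hierarchy."""


class TethercapError(Exception):
    """Base class for all package errors."""


class ValidationError(TethercapError, ValueError):
    """A physical parameter or input record is invalid."""


class DegenerateGeometryError(TethercapError, ValueError):
    """The capture/injection/outer radii do not define a proper shell."""


class NumericalError(TethercapError, ArithmeticError):
    """A quadrature or linear solve failed its accuracy check."""


class FitError(TethercapError, RuntimeError):
    """Least-squares fitting failed to converge or is non-identifiable."""
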