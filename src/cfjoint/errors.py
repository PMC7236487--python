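"""Exception hierarchy shared across the package."""


class CfjointError(Exception):
    """Base class for all package errors."""


class SchemaError(CfjointError):
    """An input table is missing required columns or has an unusable layout."""


class ReferentialError(CfjointError):
    """A record refers to an entity that does not exist (e.g. unknown patient)."""


class CohortValidationError(CfjointError):
    """A cohort violates a structural invariant (names the offending patient)."""


class ParameterError(CfjointError, ValueError):
    """An argument is outside its admissible range."""


class KnotError(CfjointError, ValueError):
    """Spline knots cannot be placed from the data provided."""


class DimensionError(CfjointError, ValueError):
    """Coefficient / design dimensions do not agree."""


class NumericalError(CfjointError, ArithmeticError):
    """A non-finite quantity appeared where a finite one is required."""
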