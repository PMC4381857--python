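"""Exception hierarchy for the nirpowder package.

All package-raised errors derive from :class:`NirPowderError` so that
pipeline code can catch "expected" failures (degenerate spectra, singular
kernel systems, ...) per screening cell without masking genuine bugs.
"""


class NirPowderError(Exception):
    """Base class for all errors raised by nirpowder."""


class SpectraFormatError(NirPowderError, ValueError):
    """A spectra file (CSV or JCAMP-DX) violates the expected layout."""


class UnsupportedUnitError(SpectraFormatError):
    """A JCAMP-DX block declares x-units other than wavenumber (1/CM)."""


class AlignmentError(NirPowderError, ValueError):
    """Sample identifiers of two containers cannot be aligned one-to-one."""


class ParameterError(NirPowderError, ValueError):
    """A user-supplied parameter is outside its valid domain."""


class DomainError(NirPowderError, ValueError):
    """Input data lie outside the mathematical domain of a transform."""


class DegenerateInputError(NirPowderError, ValueError):
    """Input data are degenerate for the requested operation
    (constant spectrum, zero-variance response, vanishing MSC slope...)."""


class ConditioningError(NirPowderError, ArithmeticError):
    """A linear system could not be solved to the required tolerance."""


class TuningError(NirPowderError, RuntimeError):
    """Hyperparameter search failed to find a finite objective value."""


class LineageError(NirPowderError, ValueError):
    """Prediction-time data do not share the pretreatment lineage of the
    data a model was trained on."""
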