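"""Exception hierarchy for kappaml.

All errors raised on invalid user input derive from :class:`KappamlError`,
which itself derives from ``ValueError`` so that callers who do not care
about the distinction can catch the standard type.
"""


class KappamlError(ValueError):
    """Base class for all kappaml input errors."""


class EmptyRatingsError(KappamlError):
    """Raised when a ratings table contains no cases."""


class UnknownLabelError(KappamlError):
    """Raised when a rating label is not a member of the category set."""


class DegenerateMarginalsError(KappamlError):
    """Raised when chance agreement equals 1 and kappa is undefined.

    For Cohen's kappa this happens when both raters assign every case to
    the same single category: Pc = 1 and (Pa - Pc)/(1 - Pc) is 0/0.
    """


class UnsupportedCategoriesError(KappamlError):
    """Raised when an estimator does not support the given category count."""


class ParseError(KappamlError):
    """Raised when an input file cannot be parsed; carries a line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
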