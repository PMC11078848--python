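"""Exception hierarchy for fluorescence-angiography quantification.

All errors derive from :class:`IcgfaError` (a ``ValueError``), so callers can
catch either the library root or the builtin.
"""


class IcgfaError(ValueError):
    """Root of the package's error hierarchy."""


class InvalidParameterError(IcgfaError):
    """A configuration or model parameter violates its invariants."""


class InvalidInputError(IcgfaError):
    """Input data (trace, stack, table) is unusable for the operation."""


class BoundsError(IcgfaError):
    """A region of interest extends beyond the frame."""


class NoOnsetError(IcgfaError):
    """No sample ever exceeds the baseline threshold; onset undetectable."""


class DegenerateRangeError(IcgfaError):
    """Fmax <= F0: the intensity range is empty, normalization undefined."""


class InvalidIntervalError(IcgfaError):
    """A time interval has non-positive length."""


class InsufficientDataError(IcgfaError):
    """Too few cases/samples for the requested statistic."""


class DegeneratePairError(IcgfaError):
    """A pair mean of zero makes the relative difference undefined."""

    def __init__(self, message: str, case_ids=None):
        super().__init__(message)
        self.case_ids = list(case_ids) if case_ids is not None else []


class DegenerateRegressorError(IcgfaError):
    """The regressor has zero variance; OLS slope undefined."""


class ZeroVarianceError(IcgfaError):
    """Constant input where a distributional test needs spread."""


class DegenerateReferenceError(IcgfaError):
    """Percent deviation against a zero reference value."""
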