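"""Exception hierarchy for crcal."""


class CrcalError(Exception):
    """Base class for all crcal errors."""


class DataError(CrcalError):
    """Base class for load-time validation errors of competing-risk data."""


class MissingColumnError(DataError):
    """A named column is absent from the input file."""


class NonNumericTimeError(DataError):
    """The follow-up time column contains non-numeric values."""


class NonPositiveTimeError(DataError):
    """A follow-up time is zero or negative."""


class StatusCodeError(DataError):
    """A status code is outside {0, 1, 2}."""


class DuplicateIdError(DataError):
    """Subject identifiers are not unique."""


class MissingValueError(DataError):
    """A covariate column contains missing values."""


class KnotDegeneracyError(CrcalError):
    """Knot placement failed: too few distinct values or tied percentiles."""


class DegenerateWeightError(CrcalError):
    """IPCW weight undefined: censoring survival is zero at a competing event."""


class ConvergenceError(CrcalError):
    """The secondary calibration model failed to converge.

    Carries the offending :class:`~crcal.finegray.FineGrayFit` in ``fit``.
    """

    def __init__(self, message, fit=None):
        super().__init__(message)
        self.fit = fit


class BinDegeneracyError(CrcalError):
    """Quantile binning produced an empty bin after tie handling."""
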