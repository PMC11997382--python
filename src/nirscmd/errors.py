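"""Exception hierarchy for the nirscmd pipeline."""


class NirsCmdError(Exception):
    """Base class for all nirscmd errors."""


class InvalidParadigmError(NirsCmdError, ValueError):
    """Block-paradigm parameters are inconsistent or non-positive."""


class InvalidParameterError(NirsCmdError, ValueError):
    """A numeric parameter is outside its admissible range."""


class ReproducibilityError(NirsCmdError, ValueError):
    """A stochastic operation was invoked without an explicit seed."""


class InvalidIntensityError(NirsCmdError, ValueError):
    """Raw intensities contain non-positive values."""


class QualityError(NirsCmdError):
    """Signal-quality failure."""


class AllChannelsRejectedError(QualityError):
    """Every channel failed the coefficient-of-variation screen."""


class UndefinedCVError(NirsCmdError, ValueError):
    """Coefficient of variation is undefined (zero mean or empty series)."""


class InvalidFilterError(NirsCmdError, ValueError):
    """Band-pass corner frequencies are inconsistent with the sampling rate."""


class ConfigurationError(NirsCmdError):
    """Static configuration (e.g. extinction table) is unusable."""


class MissingROIError(NirsCmdError):
    """An ROI has no retained channels for this recording."""


class EpochingError(NirsCmdError, ValueError):
    """Recording does not cover the requested epoch span."""


class WindowError(NirsCmdError, ValueError):
    """Feature window falls outside the epoch."""


class FoldError(NirsCmdError, ValueError):
    """Cross-validation fold count exceeds the number of subjects."""


class PredictionError(NirsCmdError):
    """A subject's feature vector is incomplete for the trained model."""


class EmptyCohortError(NirsCmdError, ValueError):
    """No subject records supplied."""
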