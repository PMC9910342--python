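"""Exception hierarchy for the vocalps package."""


class VocalPsError(Exception):
    """Base class for all vocalps errors."""


class InvalidCalibrationError(VocalPsError):
    """Calibration line is unusable (e.g. zero slope)."""


class DegenerateFitError(VocalPsError):
    """Regression fit is degenerate (no variance in the predictor)."""


class AlignmentUndefinedError(VocalPsError):
    """Cross-correlation alignment undefined (zero-energy input)."""


class UndefinedSplError(VocalPsError):
    """SPL requested for a zero-energy window."""


class UnvoicedFrameError(VocalPsError):
    """No periodicity peak above the floor; frame is unvoiced."""


class MissingReferenceError(VocalPsError):
    """No intraoral-pressure plateau adjacent to a vowel segment."""


class InvalidParamsError(VocalPsError):
    """Inverse-filter parameters violate their physical bounds."""


class InsufficientDataError(VocalPsError):
    """Segment too short for the requested analysis."""


class UndefinedFeaturesError(VocalPsError):
    """No complete glottal cycles found; waveform features undefined."""


class MissingFeatureError(VocalPsError):
    """A model's selected feature is absent from the provided features."""


class UndefinedStatisticError(VocalPsError):
    """Statistic undefined (empty series or zero variance)."""


class ConfigurationError(VocalPsError):
    """A required participant artifact (mapping, params, model) is missing."""
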