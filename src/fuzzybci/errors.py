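"""Exception and warning types raised across the package."""


class FuzzyBCIError(Exception):
    """Base class for all package-specific errors."""


class RecordingValidationError(FuzzyBCIError, ValueError):
    """A recording or window violates a structural invariant."""


class RaggedRowError(FuzzyBCIError, ValueError):
    """A tabular EEG file has a row with a missing or extra field."""


class NonNumericCellError(FuzzyBCIError, ValueError):
    """A tabular EEG file contains a cell that does not parse as a number."""


class NonFiniteValueError(FuzzyBCIError, ValueError):
    """Data contains NaN or infinite samples."""


class RecordingTooShortError(FuzzyBCIError, ValueError):
    """Recording shorter than one analysis window."""


class BinRangeError(FuzzyBCIError, ValueError):
    """Requested spectral bin count exceeds the transform's unique bins."""


class SingleClassError(FuzzyBCIError, ValueError):
    """Feature ranking requires at least two distinct classes."""


class FeatureCountError(FuzzyBCIError, ValueError):
    """Requested more features than are available."""


class ClusterCountError(FuzzyBCIError, ValueError):
    """Fewer samples than requested clusters/rules."""


class InvalidWidthError(FuzzyBCIError, ValueError):
    """A Gaussian membership width is not strictly positive."""


class ToneFrequencyError(FuzzyBCIError, ValueError):
    """A synthetic tone lies outside the representable feature band."""


class TrainingDivergedError(FuzzyBCIError, RuntimeError):
    """Training loss became non-finite."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"training diverged at epoch {epoch}")


class ConfigError(FuzzyBCIError, ValueError):
    """Invalid run configuration value."""


class SmallClassWarning(UserWarning):
    """A class has fewer members than the requested number of CV folds."""
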