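"""Exception hierarchy shared across the toolkit."""


class EcgKitError(Exception):
    """Base class for all ecgkit errors."""


class InvalidConfigError(EcgKitError, ValueError):
    """A configuration value violates its documented precondition."""


class InvalidNoiseError(InvalidConfigError):
    """A noise specification lies outside its physical frequency band."""


class NyquistError(InvalidConfigError):
    """A filter cutoff or mains frequency is not representable at this sampling rate."""


class TooShortError(EcgKitError, ValueError):
    """The input signal is too short for the requested operation."""


class UnsupportedOrderError(InvalidConfigError):
    """Requested Daubechies order outside the supported range."""


class InvalidLevelError(InvalidConfigError):
    """A decomposition level index outside the tree's range."""


class CorruptTreeError(EcgKitError, ValueError):
    """A wavelet-packet tree is structurally inconsistent."""


class IncompatibleTreesError(EcgKitError, ValueError):
    """Two trees do not share the same structure."""


class NoBeatsError(EcgKitError, ValueError):
    """No R peaks supplied where at least one is required."""


class InsufficientDataError(EcgKitError, ValueError):
    """Not enough beats/intervals to compute the requested statistic."""


class MissingFeatureError(EcgKitError, KeyError):
    """A required feature is absent from a feature vector."""


class EmptyDatasetError(EcgKitError, ValueError):
    """A dataset with zero samples was supplied for training."""


class ShapeError(EcgKitError, ValueError):
    """Array shapes are inconsistent with each other or with training."""


class StratificationError(EcgKitError, ValueError):
    """Fold count exceeds the smallest class size."""


class FormatError(EcgKitError, ValueError):
    """A file does not conform to the expected on-disk format."""


class EmptyInputError(FormatError):
    """An input file contains no samples."""


class IoError(EcgKitError, OSError):
    """A required file is missing or unreadable."""


class PipelineStageError(EcgKitError, RuntimeError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
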