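"""Exception hierarchy shared across the package."""


class RhythmRecError(Exception):
    """Base class for all package errors."""


class ValidationError(RhythmRecError, ValueError):
    """A patient record or outcome record failed validation."""


class MissingFieldError(ValidationError):
    def __init__(self, field: str):
        self.field = field
        super().__init__(f"missing required field: {field!r}")


class OutOfRangeError(ValidationError):
    def __init__(self, field: str, value, lo, hi):
        self.field = field
        self.value = value
        self.lo = lo
        self.hi = hi
        super().__init__(
            f"field {field!r} value {value!r} outside allowed range [{lo}, {hi}]"
        )


class EmptyCohortError(RhythmRecError, ValueError):
    """An operation that needs at least one record got none."""


class UnlabeledRecordError(RhythmRecError, ValueError):
    """A supervised-training record lacks an expert action label."""


class ZeroVarianceError(RhythmRecError, ValueError):
    def __init__(self, field: str):
        self.field = field
        super().__init__(f"continuous feature {field!r} has zero variance in the cohort")


class DimensionMismatchError(RhythmRecError, ValueError):
    """A feature vector or weight matrix has the wrong shape."""


class ScalerMismatchError(RhythmRecError, ValueError):
    """Two models expected to share a feature scaler do not."""


class EmptyBatchError(RhythmRecError, ValueError):
    """A batch update was requested with no experiences."""


class WorldConfigError(RhythmRecError, ValueError):
    """A synthetic world configuration is invalid."""


class ModelFormatError(RhythmRecError, ValueError):
    """A serialized model file is corrupt or has an unsupported version."""


class CsvFormatError(RhythmRecError, ValueError):
    """A CSV file does not conform to the documented schema."""
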