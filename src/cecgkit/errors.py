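"""Exception types shared across the package."""


class CecgError(Exception):
    """Base class for package errors."""


class InvalidParameterError(CecgError, ValueError):
    """A numeric parameter violates its contract (sign, range, ...)."""


class InvalidTemplateError(CecgError, ValueError):
    """A beat template violates its structural invariants."""


class InvalidLabelError(CecgError, ValueError):
    """An unknown quality or position label was supplied."""


class CapacityError(CecgError, ValueError):
    """A generation request would exceed the configured record-length cap."""


class InvalidBandError(CecgError, ValueError):
    """A filter band lies outside (0, Nyquist)."""


class InvalidSignalError(CecgError, ValueError):
    """A signal contains non-finite samples or is otherwise unusable."""


class InvalidOverlapError(CecgError, ValueError):
    """Segmentation overlap implies a zero step."""


class ZeroVarianceError(CecgError, ValueError):
    """A segment has (numerically) zero variance and cannot be z-scored."""


class MissingAnnotationError(CecgError, ValueError):
    """A record lacks truth intervals and unlabeled data were not allowed."""


class ConfigurationError(CecgError, ValueError):
    """Inconsistent model / data / config combination."""


class TrainingDivergenceError(CecgError, RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, message, history=None):
        super().__init__(message)
        self.history = history


class EmptyTaskError(CecgError, ValueError):
    """A task admitted no segments (e.g. position task with no C1 labels)."""
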