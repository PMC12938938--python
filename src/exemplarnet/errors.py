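"""Exception hierarchy used across the pipeline."""


class ExemplarNetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ExemplarNetError, ValueError):
    """An invalid specification or parameter combination."""


class InputError(ExemplarNetError, ValueError):
    """An input array or file does not match the expected geometry/labels."""


class DataError(ExemplarNetError, ValueError):
    """A dataset violates a precondition (empty class, single class, ...)."""


class FormatError(ExemplarNetError, ValueError):
    """A serialized artifact is corrupt or structurally incompatible."""


class TrainingDivergenceError(ExemplarNetError, RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite training loss at epoch {epoch}")
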