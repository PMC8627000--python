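"""Exception hierarchy shared across the package."""


class BgcmfError(Exception):
    """Base class for all package errors."""


class MatrixFormatError(BgcmfError, ValueError):
    """A file could not be parsed as a labeled matrix of the expected form."""


class MatrixValidationError(BgcmfError, ValueError):
    """A parsed matrix violates a structural invariant (labels, symmetry, range)."""


class LabelError(BgcmfError, KeyError):
    """An identifier was not found, or label sets disagree between inputs."""


class ParameterError(BgcmfError, ValueError):
    """A hyperparameter is outside its admissible range."""


class DivergenceError(BgcmfError, ArithmeticError):
    """An iterative solver produced non-finite values."""


class PipelineStageError(BgcmfError, RuntimeError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
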