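"""Exception hierarchy shared across the package."""


class TbsegError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(TbsegError, ValueError):
    """An input violates a documented precondition or type invariant."""


class GridMismatchError(ValidationError):
    """Two grids that must share shape/spacing/origin/orientation do not."""


class FormatError(TbsegError, ValueError):
    """A file exists but does not contain what the reader expects."""


class UndefinedMetricError(TbsegError, ArithmeticError):
    """A metric is mathematically undefined for the given masks (e.g. empty)."""


class TrainingDivergenceError(TbsegError, RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int, loss: float):
        self.epoch = epoch
        self.loss = loss
        super().__init__(f"non-finite loss {loss!r} at epoch {epoch}")
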