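"""Exception hierarchy shared across the toolkit."""


class ScatterCTError(Exception):
    """Base class for all scatterct errors."""


class InvalidArgumentError(ScatterCTError, ValueError):
    """An argument violates a precondition (wrong sign, shape, or range)."""


class OutOfBoundsError(ScatterCTError, IndexError):
    """A requested window or coordinate falls outside the available array."""


class CapacityError(ScatterCTError, ValueError):
    """More unique items were requested than exist."""


class DegenerateInputError(ScatterCTError, ValueError):
    """Input is constant / zero-variance where variation is required."""


class DegenerateSystemError(ScatterCTError, ValueError):
    """The linear system is identically zero or otherwise unsolvable."""


class OptimizationFailureError(ScatterCTError, RuntimeError):
    """An iterative solve produced non-finite values.

    Carries ``last_finite_step`` when known.
    """

    def __init__(self, message: str, last_finite_step: int | None = None):
        super().__init__(message)
        self.last_finite_step = last_finite_step


class StageError(ScatterCTError, RuntimeError):
    """A pipeline stage failed; names the stage and preserves the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
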