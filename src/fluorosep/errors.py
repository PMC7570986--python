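"""Exception hierarchy shared by all stages.

Validation errors (bad inputs, malformed tables) and computation errors
(degenerate geometry, singular covariances) map to distinct CLI exit codes.
"""


class FluorosepError(Exception):
    """Base class for all package errors."""


class ValidationError(FluorosepError):
    """Input data or configuration violates a documented precondition."""


class ComputationError(FluorosepError):
    """A numerically degenerate situation was encountered mid-computation."""


class StageError(FluorosepError):
    """Wraps an error with the pipeline stage in which it occurred."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"[{stage}] {cause}")
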