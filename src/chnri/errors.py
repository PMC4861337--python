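"""Exception hierarchy.

Validation errors (bad input data or survey design) are distinguished from
computation errors (a statistic is undefined or a procedure degenerate) so the
command-line layer can map them to distinct exit codes.
"""


class ChnriError(Exception):
    """Base class for all package errors."""


class ValidationError(ChnriError):
    """Raised when input data, a design, or a configuration is invalid."""


class ComputationError(ChnriError):
    """Raised when a requested statistic is undefined or a procedure is degenerate."""


class StageError(ChnriError):
    """Pipeline failure wrapping the underlying error with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"[{stage}] {cause}")
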