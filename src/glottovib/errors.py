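"""Exception hierarchy for the glottovib pipeline."""


class GlottovibError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(GlottovibError, ValueError):
    """A parameter violates an operation's precondition."""


class SchemaError(GlottovibError, ValueError):
    """Trial metadata is missing a field or is internally inconsistent."""


class InsufficientDataError(GlottovibError, ValueError):
    """Too few data points to compute the requested statistic."""


class DegenerateInputError(GlottovibError, ValueError):
    """Input is structurally unusable (e.g. an all-undefined edge track)."""


class StageError(GlottovibError, RuntimeError):
    """A pipeline stage failed; carries the stage name and trial id."""

    def __init__(self, stage: str, trial_id: str, cause: BaseException):
        self.stage = stage
        self.trial_id = trial_id
        super().__init__(f"stage '{stage}' failed for trial '{trial_id}': {cause}")
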