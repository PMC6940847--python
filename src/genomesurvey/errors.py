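"""Exception hierarchy for the survey toolkit."""


class SurveyError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(SurveyError, ValueError):
    """A parameter or object violates its contract; message names the field."""


class FormatError(SurveyError, ValueError):
    """Malformed input data (bad alphabet, seq/qual length mismatch, ...)."""


class EstimationError(SurveyError, RuntimeError):
    """An estimator could not produce a value (empty input, degenerate fit)."""


class ConfigurationError(SurveyError, ValueError):
    """A pipeline configuration is incomplete or inconsistent."""


class StageError(SurveyError, RuntimeError):
    """A pipeline stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause!r}")
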