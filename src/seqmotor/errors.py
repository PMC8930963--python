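"""Exception hierarchy used across the pipeline."""


class SeqMotorError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(SeqMotorError, ValueError):
    """An argument violates an operation's preconditions."""


class MatchingError(SeqMotorError):
    """Control-sequence construction could not satisfy the matching
    constraints; carries the per-constraint relative deviations."""

    def __init__(self, message: str, deviations: dict | None = None):
        super().__init__(message)
        self.deviations = deviations or {}


class DegenerateTrialError(SeqMotorError):
    """A trial cannot be scored (zero variance, insufficient overlap)."""


class ConfigurationError(SeqMotorError):
    """A schedule/config table is missing required cells or is malformed."""


class DesignError(SeqMotorError):
    """A statistical design is degenerate (missing groups/levels)."""


class DataCompletenessError(SeqMotorError):
    """Required observations are missing from the input table."""
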