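"""Exception hierarchy.

Exit-code mapping used by the CLI: ValidationError -> 2 (bad input data),
ConfigurationError and RuleParseError -> 3 (bad configuration artifacts).
"""


class FuzzyhaemError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(FuzzyhaemError):
    """Malformed reference configuration (schema violation, bad partition)."""


class CalibrationError(ConfigurationError):
    """A transition-band calibration anchor is infeasible."""


class ValidationError(FuzzyhaemError):
    """Invalid patient record or record file; names the row/field."""


class RuleParseError(FuzzyhaemError):
    """Rule-file text does not conform to the rule grammar."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at token position {position})"
        super().__init__(message)


class InferenceError(FuzzyhaemError):
    """A rule references a parameter that was never fuzzified."""


class EvaluationError(FuzzyhaemError):
    """Records and predictions cannot be aligned for evaluation."""


class GenerationError(FuzzyhaemError):
    """Synthetic-cohort generation is impossible (e.g. missing signature)."""
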