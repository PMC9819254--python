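"""Exception hierarchy for the fuzzydose package."""


class FuzzyDoseError(Exception):
    """Base class for all package errors."""


class DomainError(FuzzyDoseError):
    """A crisp input lies outside the variable's universe (beyond clamp tolerance)."""


class ConfigurationError(FuzzyDoseError):
    """A system definition is inconsistent (unknown term, missing representative, ...)."""


class NoApplicableRuleError(FuzzyDoseError):
    """No rule fired with positive strength; defuzzification is undefined."""


class NotApplicableError(FuzzyDoseError):
    """Stage-2 dosing requested for a patient not classified unhealthy."""


class StreamFormatError(FuzzyDoseError):
    """A vitals stream file contains a malformed row."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
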