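"""Exception types shared across the package."""


class PracticeError(ValueError):
    """Base class for all domain errors raised by this package."""


class EligibilityError(PracticeError):
    """Patient does not meet the eligibility constraints (age >= 18 years)."""


class DataCompletenessError(PracticeError):
    """A required field is missing or undefined.

    Carries the offending field name(s) so callers can report exactly what
    must be supplied.
    """

    def __init__(self, fields, message: str | None = None):
        if isinstance(fields, str):
            fields = [fields]
        self.fields = list(fields)
        super().__init__(message or f"missing or undefined field(s): {', '.join(self.fields)}")


class InfeasibleConstraintError(PracticeError):
    """A constraint set admits no eligible patient."""


class NotEvaluableError(PracticeError):
    """A quantity has an empty denominator and cannot be evaluated."""
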