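"""Exception hierarchy.

The CLI maps these onto exit codes: input/validation problems exit 2,
configuration problems exit 3.
"""


class HealthIndexError(Exception):
    """Base class for all package errors."""


class InputValidationError(HealthIndexError):
    """A respondent record or questionnaire response failed validation."""


class EligibilityError(InputValidationError):
    """Respondent does not meet the eligibility rules (age >= 18)."""


class MissingQuestionnaireError(InputValidationError):
    """A required questionnaire is absent from the record."""


class UnscorableDomainError(InputValidationError):
    """Every factor of a domain is missing, so the domain has no score."""


class ConfigError(HealthIndexError):
    """The scoring configuration is malformed or violates an invariant."""
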