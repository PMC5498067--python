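"""Exception hierarchy for the nitrogen-budget pipeline."""


class NBudgetError(Exception):
    """Base class for all package errors."""


class SchemaError(NBudgetError):
    """A required column is missing or the table layout is unusable."""


class ValidationError(NBudgetError):
    """A record or dataset violates a documented invariant."""


class ParameterError(NBudgetError):
    """A coefficient is out of range, unknown, or inconsistent."""


class ConfigurationError(NBudgetError):
    """A model configuration gap, e.g. no deposition rate for a year."""


class AllocationError(NBudgetError):
    """Fertilizer N cannot be apportioned between land classes."""
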