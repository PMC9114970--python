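"""Exception hierarchy shared across the package."""


class CommvarError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CommvarError):
    """A configuration object violates one of its invariants."""


class GenerationError(CommvarError):
    """Synthetic-data generation cannot proceed (e.g. empty type pool)."""


class InputError(CommvarError):
    """An input table is empty, malformed or too small for the operation."""


class ValidationError(InputError):
    """Row-level schema validation failed; message lists offending rows."""


class DesignError(CommvarError):
    """A model design matrix cannot be built (missing column, degenerate factor)."""


class FitError(CommvarError):
    """Model fitting is impossible (constant response, singular design)."""


class ContrastError(CommvarError):
    """A permutation contrast is degenerate (a label class is empty)."""


class UsageError(CommvarError):
    """Operations combined incompatibly (non-nested models, absent level)."""
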