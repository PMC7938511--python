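"""Exception hierarchy for voe.

All errors derive from :class:`VoeError` so callers can catch the package's
failures with a single except clause; the subclasses distinguish schema
problems from numerical/degenerate-data problems.
"""


class VoeError(Exception):
    """Base class for all voe errors."""


class SchemaError(VoeError):
    """The variable schema is malformed or inconsistent with the data."""


class CohortValidationError(VoeError):
    """Cohort values violate an invariant (event coding, negative time, ...)."""


class DegenerateVariableError(VoeError):
    """A variable is unusable for the requested operation (e.g. constant)."""


class EstimationError(VoeError):
    """Model fitting failed beyond the tolerated degree."""


class InsufficientDataError(VoeError):
    """Too few values to compute the requested summary."""
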