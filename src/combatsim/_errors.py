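"""Exception hierarchy shared across the package."""


class CombatSimError(Exception):
    """Base class for all package errors."""


class CovarianceError(CombatSimError):
    """A covariance matrix is not symmetric positive semidefinite."""


class DegenerateFeatureError(CombatSimError):
    """A feature has zero spread (IQR or variance), so the operation is undefined."""


class SchemaError(CombatSimError):
    """A file does not conform to the package CSV schema."""


class ValidationError(CombatSimError):
    """Input values violate an operation's preconditions."""
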