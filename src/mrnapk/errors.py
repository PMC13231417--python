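"""Exception hierarchy shared across the package."""


class MrnapkError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(MrnapkError):
    """A required column is missing or the column mapping is inconsistent."""


class ValidationError(MrnapkError, ValueError):
    """A dataset or record violates a structural invariant."""


class DesignError(MrnapkError):
    """An estimation problem is ill-posed (unidentifiable or underdetermined)."""


class ConfigurationError(MrnapkError):
    """A scaling / fitting configuration is incomplete or contradictory."""


class DegenerateSystemError(MrnapkError):
    """Closed-form solution refused because system eigenvalues are too close."""
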