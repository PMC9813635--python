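"""Exception hierarchy.

All package errors derive from :class:`SaltImpactError`; the validation
errors additionally subclass :class:`ValueError` so generic callers can
catch them without importing this module.
"""


class SaltImpactError(Exception):
    """Base class for all errors raised by saltimpact."""


class ConfigError(SaltImpactError, ValueError):
    """An invalid configuration field; the message names the field."""


class SchemaError(SaltImpactError, ValueError):
    """A table is structurally wrong (missing column, non-numeric cell)."""


class RangeError(SaltImpactError, ValueError):
    """A numeric field is outside its permitted range."""


class DuplicateKeyError(SaltImpactError, ValueError):
    """Two strata share the same (region, sex, age_band) key."""


class DomainError(SaltImpactError, ValueError):
    """A function argument is outside its mathematical domain."""


class StratumMismatchError(SaltImpactError, ValueError):
    """Two tables do not cover the same strata; the message lists them."""
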