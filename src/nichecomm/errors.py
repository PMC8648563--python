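"""Exception hierarchy shared across the package."""


class NichecommError(Exception):
    """Base class for all package errors."""


class SchemaError(NichecommError):
    """An input table is missing a required column or has a malformed header."""


class IntegrityError(NichecommError):
    """Referential integrity of the interaction database is violated."""


class CurationError(NichecommError):
    """A curation action references an unknown id or duplicates an existing one."""


class PartnerLookupError(NichecommError, KeyError):
    """An interaction partner id cannot be resolved in the database."""


class MissingGeneError(NichecommError, KeyError):
    """A database gene is absent from the expression matrix / summary."""


class DegenerateInputError(NichecommError, ValueError):
    """Input is structurally valid but statistically unusable (e.g. zero-count cell)."""


class ConfigError(NichecommError, ValueError):
    """A run or simulation configuration is invalid."""
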