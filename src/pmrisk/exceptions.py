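"""Exception hierarchy for the pmrisk pipeline."""


class PmriskError(Exception):
    """Base class for all pmrisk errors."""


class SchemaError(PmriskError):
    """An input table is missing required columns or has a malformed layout."""


class ValidationError(PmriskError):
    """A value violates a domain invariant (negative concentration, etc.)."""


class ConfigurationError(PmriskError):
    """A configuration file or registry is incomplete or inconsistent."""


class UndefinedFractionError(ValidationError):
    """Bioaccessible fraction requested with zero total concentration."""


class DepositionLookupError(PmriskError):
    """A cohort is absent from a deposition-fraction override table."""


class NotACarcinogenError(PmriskError):
    """ILCR requested for a metal with no cancer slope factor."""
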