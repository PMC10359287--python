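"""Exception hierarchy shared across the package."""


class SeathermError(Exception):
    """Base class for all package errors."""


class SchemaError(SeathermError):
    """An input table is missing a required column or has a malformed header."""


class ValidationError(SeathermError):
    """A record violates a domain invariant (negative biomass, duplicates...)."""


class TaxonLookupError(SeathermError, KeyError):
    """A taxon referenced by a sample is absent from the catalog."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return Exception.__str__(self)


class DesignError(SeathermError):
    """The sampling design is unbalanced or otherwise unusable for an analysis."""


class UndefinedValueError(SeathermError):
    """A statistic is mathematically undefined for the given input."""
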