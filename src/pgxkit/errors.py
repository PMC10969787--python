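"""Exception hierarchy shared across pgxkit modules."""


class PgxError(Exception):
    """Base class for all pgxkit errors."""


class CatalogValidationError(PgxError):
    """The knowledge-base file violates its schema or invariants."""


class UnknownGeneError(PgxError):
    """A gene symbol is not present in the loaded knowledge base."""


class UnknownAlleleError(PgxError):
    """A star allele is not defined for the given gene."""


class UnknownDrugError(PgxError):
    """A drug is not associated with the selected gene."""


class VcfParseError(PgxError):
    """A VCF record could not be parsed; carries an approximate line number."""
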