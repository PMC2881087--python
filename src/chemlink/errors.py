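"""Exception hierarchy for chemlink."""


class ChemLinkError(Exception):
    """Base class for all chemlink errors."""


class SchemaParseError(ChemLinkError):
    """The schema config file could not be parsed."""


class SchemaValidationError(ChemLinkError):
    """The schema config parsed but violates a structural invariant."""


class UnknownClassError(ChemLinkError, LookupError):
    """A referenced entity class is not declared in the schema."""


class PathCompilationError(ChemLinkError):
    """A link path cannot be compiled to SPARQL (e.g. zero-length path)."""


class QueryError(ChemLinkError):
    """A SPARQL query is malformed or refers to a missing variable."""


class StructureParseError(ChemLinkError):
    """A SMILES string could not be parsed into a molecule."""

    def __init__(self, structure: str):
        self.structure = structure
        super().__init__(f"could not parse structure: {structure!r}")


class DimensionError(ChemLinkError, ValueError):
    """Fingerprints of incompatible lengths were compared."""


class IntegrityError(ChemLinkError):
    """Conflicting records violate a uniqueness constraint."""


class UnknownSourceError(ChemLinkError, LookupError):
    """A named data source has no records in the store."""
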