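"""Homogeneous-source integration statistics.

When several sources publish the same *kind* of record (protein-protein
interactions, pathway memberships, chemical-protein interactions), each
source's value is measured as the share of the integrated union it covers:
``100 * |source records| / |union records|``, rounded half-up to one decimal.
Records are canonicalized before set arithmetic so the same fact reported
twice (e.g. a PPI in either order, or a chemical-protein interaction seen in
several assays) counts once.

The linkage experiment measures the complementary benefit for *linking*:
how many drug -> gene -> pathway chains survive when only a subset of the
chemogenomics and pathway sources is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

from rdflib import RDF, URIRef

from .errors import UnknownSourceError
from .schema import SchemaGraph, default_schema
from .store import TripleStore
from .vocab import VOCAB, local_id


def canonicalize_ppi(a: str, b: str) -> tuple[str, str]:
    """Order-free canonical form of a protein interaction pair."""
    if not a or not b:
        raise ValueError("protein identifiers must be non-empty")
    return (a, b) if a <= b else (b, a)


def canonicalize_chem_interaction(cid: int, accession: str) -> tuple[int, str]:
    """Canonical chemical-protein interaction: one entry per (CID, protein),
    regardless of how many assays or rows report it."""
    return (int(cid), accession)


@dataclass(frozen=True)
class RecordSet:
    """Canonical records contributed by one source."""

    source_name: str
    records: frozenset

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class SourceContribution:
    source_name: str
    unique_count: int
    percentage: float  # of the union, 1 decimal


@dataclass(frozen=True)
class ContributionTable:
    sources: tuple[SourceContribution, ...]
    union_count: int

    def as_rows(self) -> list[tuple[str, int, float]]:
        return [(s.source_name, s.unique_count, s.percentage) for s in self.sources]


def _pct(count: int, union: int) -> float:
    frac = Decimal(100) * Decimal(count) / Decimal(union)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def unique_contribution(sources: Sequence[RecordSet]) -> ContributionTable:
    """Per-source share of the union of canonical records (input order kept)."""
    if not sources:
        raise ValueError("at least one record set is required")
    union: set = set()
    for s in sources:
        union |= s.records
    if not union:
        raise ValueError("union of records is empty; percentages undefined")
    contribs = tuple(
        SourceContribution(s.source_name, len(s.records), _pct(len(s.records), len(union)))
        for s in sources
    )
    return ContributionTable(contribs, len(union))


@dataclass(frozen=True)
class LinkageResult:
    path_count: int
    gene_count: int
    pathway_count: int
    sources_used: tuple[str, ...]


def _check_sources(store: TripleStore, names: Iterable[str]) -> None:
    present = store.sources_present()
    for name in names:
        if name not in present:
            raise UnknownSourceError(f"no records tagged with source {name!r} in store")


def _chem_links(store: TripleStore, schema: SchemaGraph, source: str) -> set[tuple[str, str]]:
    """(CID, gene accession) pairs asserted by one chemogenomics source.

    Records either point at a compound directly, or at a drug whose structure
    is mapped to a compound.
    """
    links: set[tuple[str, str]] = set()
    type_uri = URIRef(schema.get_class(source).type_uri)
    for record in store.graph.subjects(RDF.type, type_uri):
        genes = [local_id(g) for g in store.objects(str(record), str(VOCAB.uniprot))]
        if not genes:
            continue
        cids = [local_id(c) for c in store.objects(str(record), str(VOCAB.compound))]
        for drug in store.objects(str(record), str(VOCAB.drug)):
            cids.extend(local_id(c) for c in store.objects(str(drug), str(VOCAB.compound)))
        for cid in cids:
            for gene in genes:
                links.add((cid, gene))
    return links


def _pathway_memberships(store: TripleStore, schema: SchemaGraph, source: str) -> set[tuple[str, str]]:
    """(gene accession, pathway id) pairs asserted by one pathway source."""
    pairs: set[tuple[str, str]] = set()
    type_uri = URIRef(schema.get_class(source).type_uri)
    for record in store.graph.subjects(RDF.type, type_uri):
        genes = [local_id(g) for g in store.objects(str(record), str(VOCAB.uniprot))]
        pids = [str(p) for p in store.objects(str(record), str(VOCAB.pathway_id))]
        for gene in genes:
            for pid in pids:
                pairs.add((gene, pid))
    return pairs


def linkage_experiment(
    store: TripleStore,
    drug_ids: Sequence,
    chemogenomics_sources: Sequence[str],
    pathway_sources: Sequence[str],
    schema: SchemaGraph | None = None,
) -> LinkageResult:
    """Count distinct drug -> gene -> pathway chains reachable from the given
    drugs (as CIDs) using only the named sources.

    A chain is a distinct (CID, gene, pathway) triple; multiple records
    asserting the same chemical-protein link do not multiply the count.
    """
    schema = schema or default_schema()
    _check_sources(store, list(chemogenomics_sources) + list(pathway_sources))
    wanted = {str(d) for d in drug_ids}
    if not wanted:
        return LinkageResult(0, 0, 0, tuple(chemogenomics_sources) + tuple(pathway_sources))

    gene_links: set[tuple[str, str]] = set()
    for source in chemogenomics_sources:
        gene_links |= {(c, g) for c, g in _chem_links(store, schema, source) if c in wanted}

    memberships: set[tuple[str, str]] = set()
    for source in pathway_sources:
        memberships |= _pathway_memberships(store, schema, source)

    by_gene: dict[str, set[str]] = {}
    for gene, pid in memberships:
        by_gene.setdefault(gene, set()).add(pid)

    chains = {
        (cid, gene, pid)
        for cid, gene in gene_links
        for pid in by_gene.get(gene, ())
    }
    return LinkageResult(
        path_count=len(chains),
        gene_count=len({g for _, g, _ in chains}),
        pathway_count=len({p for _, _, p in chains}),
        sources_used=tuple(chemogenomics_sources) + tuple(pathway_sources),
    )


# -- record-set extraction from a store (CLI support) -------------------------

PPI_SOURCES = ("hprd", "dip")
CHEMOGENOMICS_SOURCES = (
    "bindingdb_interaction",
    "ctd_interaction",
    "drugbank_interaction",
    "matador",
    "pubchem_bioassay",
    "qsar",
)


def ppi_record_sets(store: TripleStore, schema: SchemaGraph | None = None,
                    sources: Sequence[str] = PPI_SOURCES) -> list[RecordSet]:
    schema = schema or default_schema()
    sets = []
    for source in sources:
        type_uri = URIRef(schema.get_class(source).type_uri)
        pairs = set()
        for record in store.graph.subjects(RDF.type, type_uri):
            a = store.objects(str(record), str(VOCAB.protein_a))
            b = store.objects(str(record), str(VOCAB.protein_b))
            if a and b:
                pairs.add(canonicalize_ppi(local_id(a[0]), local_id(b[0])))
        sets.append(RecordSet(source, frozenset(pairs)))
    return sets


def chemogenomics_record_sets(store: TripleStore, schema: SchemaGraph | None = None,
                              sources: Sequence[str] = CHEMOGENOMICS_SOURCES) -> list[RecordSet]:
    schema = schema or default_schema()
    return [
        RecordSet(source, frozenset(_chem_links(store, schema, source)))
        for source in sources
    ]


def pathway_record_sets(store: TripleStore, schema: SchemaGraph | None = None,
                        sources: Sequence[str] = ("kegg_pathway_protein", "reactome"),
                        kind: str = "protein") -> list[RecordSet]:
    """Pathway sources measured either by the distinct proteins they involve
    or by their distinct pathway records."""
    schema = schema or default_schema()
    sets = []
    for source in sources:
        pairs = _pathway_memberships(store, schema, source)
        if kind == "protein":
            records = frozenset(g for g, _ in pairs)
        elif kind == "pathway":
            records = frozenset(p for _, p in pairs)
        else:
            raise ValueError("kind must be 'protein' or 'pathway'")
        sets.append(RecordSet(source, records))
    return sets
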