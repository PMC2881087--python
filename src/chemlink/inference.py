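"""Cross-source inference algorithms over a triple store.

Three analyses, each built from a generated linked-path query plus
post-processing:

1. **Polypharmacology** — compounds whose active-assay profile shares at
   least ``min_shared`` protein targets with a reference drug.
2. **Multi-target pathway inhibition** — compounds active against at least
   ``min_targets`` distinct proteins of one pathway (chains inferred by the
   rule: compound x targets protein y, y belongs to pathway z => x relates
   to z).
3. **Side-effect -> pathway association** — an *efficient gene* is targeted
   by >= ``min_drugs_per_gene`` drugs reporting the same side effect; a
   pathway containing >= ``min_genes_per_pathway`` efficient genes is
   associated with the side effect, ranked by the number of supporting
   drug -> gene -> pathway chains.

Hits are gated on *distinct targets/genes*, not raw chain counts; chain
counts are still reported for ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .chem import MoleculeDescriptors, rule_of_five
from .errors import UnknownClassError
from .paths import (
    IdentifierEquals,
    Projection,
    PropertyFilter,
    TermIn,
    build_path,
    path_to_sparql,
)
from .schema import SchemaGraph, default_schema
from .store import TripleStore
from .vocab import VOCAB, local_id

logger = logging.getLogger("chemlink")

#: Pathway-membership record classes consulted by the pathway analyses.
PATHWAY_SOURCES = ("kegg_pathway_protein", "reactome")


@dataclass(frozen=True)
class PolypharmacologyHit:
    compound_id: int
    shared_targets: frozenset[str]
    path_count: int
    druglike: bool


@dataclass(frozen=True)
class PathwayInhibitorHit:
    compound_id: int
    pathway_id: str
    pathway_name: str
    inhibited_targets: frozenset[str]


@dataclass(frozen=True)
class CompoundPathwayChain:
    """One compound -> target -> pathway evidence chain (assay-level)."""

    compound_id: int
    target_accession: str
    pathway_id: str
    pathway_name: str
    source: str
    assay_record: str
    membership_record: str


@dataclass(frozen=True)
class PathwaySideEffectAssociation:
    pathway_id: str
    pathway_name: str
    side_effect_terms: frozenset[str]
    efficient_genes: frozenset[str]
    associative_path_count: int


def _descriptors(store: TripleStore, compound_uri: str) -> MoleculeDescriptors | None:
    values = {}
    for field, pred in (
        ("molecular_weight", VOCAB.mw),
        ("logp", VOCAB.logp),
        ("hbd_count", VOCAB.hbd),
        ("hba_count", VOCAB.hba),
    ):
        objs = store.objects(compound_uri, str(pred))
        if not objs:
            return None
        values[field] = objs[0]
    return MoleculeDescriptors(
        float(values["molecular_weight"]),
        float(values["logp"]),
        int(values["hbd_count"]),
        int(values["hba_count"]),
    )


def find_polypharmacology(
    store: TripleStore,
    drug_id: str,
    min_shared: int = 2,
    score_threshold: float = 50,
    require_druglike: bool = True,
    schema: SchemaGraph | None = None,
    emit_sparql: list | None = None,
) -> list[PolypharmacologyHit]:
    """Compounds sharing >= ``min_shared`` active targets with a drug.

    The evidence chain is drug -> drug-target interaction -> protein <-
    bioassay record -> compound, with the bioassay record required to be
    active (outcome 2, score strictly above ``score_threshold``). The drug's
    own compound is never a hit. Hits are ordered by descending number of
    shared targets, then by CID.
    """
    schema = schema or default_schema()
    drug_uri = schema.mint_uri("drugbank_drug", drug_id)
    from rdflib import URIRef

    ref = URIRef(drug_uri)
    present = any(store.triples((ref, None, None))) or any(
        store.triples((None, None, ref))
    )
    if not present:
        raise UnknownClassError(f"drug {drug_id!r} not present in the store")

    path = build_path(
        schema,
        ["drugbank_drug", "drugbank_interaction", "uniprot", "pubchem_bioassay", "compound"],
    )
    query = path_to_sparql(
        path,
        filters=[
            IdentifierEquals("drugbank_drug", drug_uri),
            PropertyFilter("pubchem_bioassay", str(VOCAB.outcome), "=", 2),
            PropertyFilter("pubchem_bioassay", str(VOCAB.score), ">", score_threshold),
        ],
        select_all=True,
        typed=True,
        graph=schema,
    )
    if emit_sparql is not None:
        emit_sparql.append(query.text)

    drug_targets = {
        t
        for i in store.subjects(str(VOCAB.drug), drug_uri)
        for t in store.objects(i, str(VOCAB.uniprot))
    }
    if not drug_targets:
        logger.warning("drug %s has no target links; empty result", drug_id)
        return []

    own_compounds = set(store.objects(drug_uri, str(VOCAB.compound)))
    rows = store.execute(query)

    per_compound: dict[str, dict] = {}
    for row in rows:
        compound_uri = row[query.terminal_var]
        if compound_uri in own_compounds:
            continue
        target_uri = row["v2"]
        entry = per_compound.setdefault(compound_uri, {"targets": set(), "chains": set()})
        entry["targets"].add(local_id(target_uri))
        entry["chains"].add(tuple(sorted((k, str(v)) for k, v in row.items())))

    hits = []
    for compound_uri, entry in per_compound.items():
        if len(entry["targets"]) < min_shared:
            continue
        descriptors = _descriptors(store, compound_uri)
        druglike = descriptors is not None and rule_of_five(descriptors).passes
        if require_druglike and not druglike:
            continue
        hits.append(
            PolypharmacologyHit(
                compound_id=int(local_id(compound_uri)),
                shared_targets=frozenset(entry["targets"]),
                path_count=len(entry["chains"]),
                druglike=druglike,
            )
        )
    hits.sort(key=lambda h: (-len(h.shared_targets), h.compound_id))
    return hits


def infer_compound_pathway(
    store: TripleStore,
    score_threshold: float = 50,
    schema: SchemaGraph | None = None,
    pathway_sources: tuple[str, ...] = PATHWAY_SOURCES,
    emit_sparql: list | None = None,
) -> list[CompoundPathwayChain]:
    """Every compound -> target -> pathway chain supported by an active assay.

    Chains are kept at assay-record granularity (no deduplication across
    assays) so downstream analyses can count evidence paths; a protein in two
    pathways yields two chains per active record.
    """
    schema = schema or default_schema()
    chains: list[CompoundPathwayChain] = []
    for source in pathway_sources:
        path = build_path(schema, ["compound", "pubchem_bioassay", "uniprot", source])
        query = path_to_sparql(
            path,
            filters=[
                PropertyFilter("pubchem_bioassay", str(VOCAB.outcome), "=", 2),
                PropertyFilter("pubchem_bioassay", str(VOCAB.score), ">", score_threshold),
            ],
            projections=[
                Projection(source, str(VOCAB.pathway_id)),
                Projection(source, str(VOCAB.pathway_name)),
            ],
            select_all=True,
            typed=True,
            graph=schema,
        )
        if emit_sparql is not None:
            emit_sparql.append(query.text)
        pid_var = query.property_vars[(source, str(VOCAB.pathway_id))]
        pname_var = query.property_vars[(source, str(VOCAB.pathway_name))]
        for row in store.execute(query):
            chains.append(
                CompoundPathwayChain(
                    compound_id=int(local_id(row["v0"])),
                    target_accession=local_id(row["v2"]),
                    pathway_id=str(row[pid_var]),
                    pathway_name=str(row[pname_var]),
                    source=source,
                    assay_record=str(row["v1"]),
                    membership_record=str(row["v3"]),
                )
            )
    chains.sort(
        key=lambda c: (c.compound_id, c.target_accession, c.pathway_id, c.assay_record)
    )
    return chains


def find_pathway_inhibitors(
    store: TripleStore,
    pathway_name_filter: str,
    min_targets: int = 2,
    score_threshold: float = 50,
    schema: SchemaGraph | None = None,
) -> list[PathwayInhibitorHit]:
    """Compounds active against >= ``min_targets`` distinct proteins of one
    pathway whose name contains the filter (case-insensitive substring)."""
    if not pathway_name_filter:
        raise ValueError("pathway name filter must be non-empty")
    needle = pathway_name_filter.lower()
    chains = [
        c
        for c in infer_compound_pathway(store, score_threshold, schema)
        if needle in c.pathway_name.lower()
    ]
    if not chains:
        logger.warning("no pathway matches %r (or no active chains)", pathway_name_filter)
        return []
    grouped: dict[tuple[int, str], dict] = {}
    for c in chains:
        entry = grouped.setdefault(
            (c.compound_id, c.pathway_id), {"targets": set(), "name": c.pathway_name}
        )
        entry["targets"].add(c.target_accession)
    hits = [
        PathwayInhibitorHit(
            compound_id=cid,
            pathway_id=pid,
            pathway_name=entry["name"],
            inhibited_targets=frozenset(entry["targets"]),
        )
        for (cid, pid), entry in grouped.items()
        if len(entry["targets"]) >= min_targets
    ]
    hits.sort(key=lambda h: (-len(h.inhibited_targets), h.compound_id, h.pathway_id))
    return hits


def count_multiply_inhibited_pathways(
    store: TripleStore,
    min_targets: int = 2,
    score_threshold: float = 50,
    schema: SchemaGraph | None = None,
) -> tuple[int, dict[str, list[tuple[int, frozenset[str]]]]]:
    """Count pathways in which >= 1 compound is active against
    >= ``min_targets`` distinct proteins; also return, per qualifying pathway,
    the qualifying compounds with their inhibited target sets."""
    chains = infer_compound_pathway(store, score_threshold, schema)
    per_pathway: dict[str, dict[int, set[str]]] = {}
    for c in chains:
        per_pathway.setdefault(c.pathway_id, {}).setdefault(c.compound_id, set()).add(
            c.target_accession
        )
    detail: dict[str, list[tuple[int, frozenset[str]]]] = {}
    for pid in sorted(per_pathway):
        qualifying = [
            (cid, frozenset(targets))
            for cid, targets in sorted(per_pathway[pid].items())
            if len(targets) >= min_targets
        ]
        if qualifying:
            detail[pid] = qualifying
    return len(detail), detail


def associate_side_effect_pathways(
    store: TripleStore,
    side_effect_terms: list[str],
    min_drugs_per_gene: int = 2,
    min_genes_per_pathway: int = 2,
    top_k: int = 5,
    schema: SchemaGraph | None = None,
    pathway_sources: tuple[str, ...] = PATHWAY_SOURCES,
    emit_sparql: list | None = None,
) -> list[PathwaySideEffectAssociation]:
    """Rank pathways associated with a side effect.

    Pipeline: drugs whose side-effect records match any of the given terms
    (case-insensitive exact term match) -> genes targeted by at least
    ``min_drugs_per_gene`` matching drugs (*efficient genes*) -> pathways
    containing at least ``min_genes_per_pathway`` efficient genes, ranked by
    the number of distinct drug -> gene -> pathway chains.
    """
    if not side_effect_terms:
        raise ValueError("side-effect term list must be non-empty")
    schema = schema or default_schema()

    # side-effect record -> drug -> interaction -> gene, filtered on the terms
    path = build_path(schema, ["sider", "drugbank_drug", "drugbank_interaction", "uniprot"])
    query = path_to_sparql(
        path,
        filters=[TermIn("sider", str(VOCAB.side_effect), tuple(side_effect_terms))],
        select_all=True,
        typed=True,
        graph=schema,
    )
    if emit_sparql is not None:
        emit_sparql.append(query.text)
    term_var = query.property_vars[("sider", str(VOCAB.side_effect))]

    drug_gene: dict[str, set[str]] = {}  # gene -> matching drugs
    drug_terms: dict[str, set[str]] = {}  # drug -> matched terms
    for row in store.execute(query):
        drug, gene = local_id(row["v1"]), local_id(row["v3"])
        drug_gene.setdefault(gene, set()).add(drug)
        drug_terms.setdefault(drug, set()).add(str(row[term_var]).lower())
    if not drug_terms:
        logger.warning("no drug matches side-effect terms %r", side_effect_terms)
        return []

    efficient = {g for g, drugs in drug_gene.items() if len(drugs) >= min_drugs_per_gene}

    # pathways containing efficient genes, via the membership record classes
    pathway_genes: dict[str, set[str]] = {}
    pathway_names: dict[str, str] = {}
    from rdflib import RDF, URIRef

    for source in pathway_sources:
        type_uri = URIRef(schema.get_class(source).type_uri)
        for membership in store.graph.subjects(RDF.type, type_uri):
            genes = store.objects(str(membership), str(VOCAB.uniprot))
            pids = store.objects(str(membership), str(VOCAB.pathway_id))
            names = store.objects(str(membership), str(VOCAB.pathway_name))
            for pid in pids:
                pid = str(pid)
                if names:
                    pathway_names[pid] = str(names[0])
                for gene_uri in genes:
                    gene = local_id(gene_uri)
                    if gene in efficient:
                        pathway_genes.setdefault(pid, set()).add(gene)

    associations = []
    for pid, genes in pathway_genes.items():
        if len(genes) < min_genes_per_pathway:
            continue
        chains = {
            (drug, gene, pid) for gene in genes for drug in drug_gene[gene]
        }
        terms = frozenset(
            t for (drug, _, _) in chains for t in drug_terms.get(drug, ())
        )
        associations.append(
            PathwaySideEffectAssociation(
                pathway_id=pid,
                pathway_name=pathway_names.get(pid, pid),
                side_effect_terms=terms,
                efficient_genes=frozenset(genes),
                associative_path_count=len(chains),
            )
        )
    associations.sort(
        key=lambda a: (-a.associative_path_count, -len(a.efficient_genes), a.pathway_id)
    )
    return associations[:top_k]
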