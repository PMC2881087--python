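"""Independent oracles the test suite (and the acceptance script) compare
the implementation against. Each oracle deliberately avoids the code path it
checks: path enumeration uses networkx over a rebuilt multigraph, the
polypharmacology oracle does straight joins over raw triples, and the
Tanimoto oracle counts bits one by one.
"""

from __future__ import annotations

import networkx as nx
from rdflib import RDF, URIRef

from chemlink.chem import rule_of_five, MoleculeDescriptors
from chemlink.schema import SchemaGraph
from chemlink.store import TripleStore
from chemlink.vocab import VOCAB, local_id


def tanimoto_bruteforce(bits_a, bits_b) -> float:
    n_a = n_b = n_c = 0
    for i in range(len(bits_a)):
        if bits_a[i] == 1:
            n_a += 1
        if bits_b[i] == 1:
            n_b += 1
        if bits_a[i] == 1 and bits_b[i] == 1:
            n_c += 1
    if n_a + n_b - n_c == 0:
        return 0.0
    return n_c / (n_a + n_b - n_c)


def enumerate_paths_networkx(graph: SchemaGraph, origin: str, terminal: str,
                             max_length: int) -> set:
    """Exhaustive simple-path enumeration via networkx, as comparable
    (classes, predicates) tuples."""
    mg = nx.MultiGraph()
    mg.add_nodes_from(graph.classes)
    for i, e in enumerate(graph.edges):
        mg.add_edge(e.source_class, e.target_class, key=i, predicate=e.predicate)
    if origin == terminal:
        return {((origin,), ())}
    found = set()
    for edge_path in nx.all_simple_edge_paths(mg, origin, terminal, cutoff=max_length):
        classes = [origin]
        preds = []
        for u, v, key in edge_path:
            nxt = v if classes[-1] == u else u
            classes.append(nxt)
            preds.append(graph.edges[key].predicate)
        found.add((tuple(classes), tuple(preds)))
    return found


def path_set(paths) -> set:
    return {(p.classes, tuple(e.predicate for e in p.edges)) for p in paths}


def polypharmacology_join_oracle(
    store: TripleStore,
    schema: SchemaGraph,
    drug_id: str,
    min_shared: int = 2,
    score_threshold: float = 50,
    require_druglike: bool = True,
) -> list[tuple[int, frozenset, int, bool]]:
    """Straight joins over raw triples; no SPARQL, no path compilation.

    Returns (cid, shared_targets, path_count, druglike) tuples in the same
    order the implementation uses.
    """
    g = store.graph
    drug_uri = URIRef(schema.mint_uri("drugbank_drug", drug_id))
    interaction_type = URIRef(schema.get_class("drugbank_interaction").type_uri)
    assay_type = URIRef(schema.get_class("pubchem_bioassay").type_uri)

    drug_targets = set()
    interactions = {}
    for rec in g.subjects(RDF.type, interaction_type):
        drugs = set(g.objects(rec, VOCAB.drug))
        targets = set(g.objects(rec, VOCAB.uniprot))
        if drug_uri in drugs:
            drug_targets |= targets
            for t in targets:
                interactions.setdefault(t, set()).add(rec)

    own = set(g.objects(drug_uri, VOCAB.compound))
    per_compound = {}
    for rec in g.subjects(RDF.type, assay_type):
        outcome = next(iter(g.objects(rec, VOCAB.outcome)), None)
        score = next(iter(g.objects(rec, VOCAB.score)), None)
        if outcome is None or int(outcome) != 2:
            continue
        if score is None or float(score) <= score_threshold:
            continue
        for target in g.objects(rec, VOCAB.uniprot):
            if target not in drug_targets:
                continue
            for compound in g.objects(rec, VOCAB.compound):
                if compound in own:
                    continue
                entry = per_compound.setdefault(compound, {"targets": set(), "chains": set()})
                entry["targets"].add(target)
                for interaction in interactions[target]:
                    entry["chains"].add((interaction, rec, target, compound))

    hits = []
    for compound, entry in per_compound.items():
        if len(entry["targets"]) < min_shared:
            continue
        vals = {}
        for name, pred in (("mw", VOCAB.mw), ("logp", VOCAB.logp),
                           ("hbd", VOCAB.hbd), ("hba", VOCAB.hba)):
            obj = next(iter(g.objects(compound, pred)), None)
            vals[name] = obj.toPython() if obj is not None else None
        druglike = None not in vals.values() and rule_of_five(
            MoleculeDescriptors(float(vals["mw"]), float(vals["logp"]),
                                int(vals["hbd"]), int(vals["hba"]))
        ).passes
        if require_druglike and not druglike:
            continue
        hits.append((
            int(local_id(str(compound))),
            frozenset(local_id(str(t)) for t in entry["targets"]),
            len(entry["chains"]),
            druglike,
        ))
    hits.sort(key=lambda h: (-len(h[1]), h[0]))
    return hits


def random_schema(rng, max_nodes: int = 8) -> SchemaGraph:
    """A random small schema with possible parallel edges, for enumeration
    equivalence checks."""
    from chemlink.schema import EntityClass, JoinEdge

    n = rng.randint(2, max_nodes)
    names = [f"cls{i}" for i in range(n)]
    classes = [
        EntityClass(name, "chemogenomics", f"http://example.org/x/{name}/")
        for name in names
    ]
    edges = []
    n_edges = rng.randint(1, 2 * n)
    for i in range(n_edges):
        a, b = rng.sample(names, 2)
        edges.append(JoinEdge(a, b, f"http://example.org/p/{rng.randint(0, 5)}", b.upper()))
    # keep join keys consistent at every target class
    fixed = [JoinEdge(e.source_class, e.target_class, e.predicate, e.target_class.upper())
             for e in edges]
    # drop duplicate (source, target, predicate) triples: parallel edges must
    # carry distinct predicates to be distinct evidence
    seen, uniq = set(), []
    for e in fixed:
        key = (e.source_class, e.target_class, e.predicate)
        if key not in seen:
            seen.add(key)
            uniq.append(e)
    return SchemaGraph(classes, uniq)
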