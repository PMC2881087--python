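"""Synthetic RDF fixture generator with planted, manifest-declared hits.

Generates a small schema-conformant chemogenomics graph (activity records
with outcome/score, drug-target links, pathway memberships, side-effect
records, molecule descriptors, PPI rows, literature co-mentions) in which
every inference algorithm has a known answer:

* one reference drug with three targets, two planted polypharmacology hits
  (sharing 2 and 3 targets) and decoys that each fail exactly one filter
  (score at or below threshold, outcome 1, a single shared target, a
  non-drug-like molecular weight);
* one pathway with two planted inhibited branch targets and one compound
  active on both, plus single-target and duplicate-assay decoys;
* a side-effect scenario with two efficient genes in one pathway (two
  matching drugs per gene) and decoys (a gene with one matching drug, a
  pathway with one efficient gene).

Identifiers, scores and noise records are drawn from a seeded RNG so repeated
generation with the same seed is byte-identical while different seeds vary
the surface of the data without moving the planted ground truth.

Descriptor values are sampled inside or outside the drug-likeness bounds by
plant design rather than computed from structures, so pipeline tests do not
depend on a chemistry engine.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path

from rdflib import RDF, Graph, Literal, URIRef

from .errors import SchemaValidationError
from .schema import SchemaGraph, default_schema
from .store import TripleStore
from .vocab import VOCAB

_SMILES_POOL = (
    "CCO",
    "CCN",
    "c1ccccc1O",
    "CC(=O)Oc1ccccc1C(=O)O",
    "CN1C=NC2=C1C(=O)N(C)C(=O)N2C",
)

_NOISE_SIDE_EFFECTS = ("headache", "nausea", "dizziness", "rash")


@dataclass
class FixtureSpec:
    """Scale and content knobs for one generated fixture."""

    seed: int = 0
    n_noise_compounds: int = 12
    n_noise_targets: int = 6
    n_noise_drugs: int = 3
    n_chem_records_per_source: int = 4
    n_ppi_records_per_source: int = 5
    side_effect_terms: tuple[str, ...] = ("hepatitis",)
    pathway_filter: str = "MAPK"

    def validate(self) -> None:
        for name in (
            "n_noise_compounds",
            "n_noise_targets",
            "n_noise_drugs",
            "n_chem_records_per_source",
            "n_ppi_records_per_source",
        ):
            if getattr(self, name) < 1:
                raise SchemaValidationError(f"{name} must be positive")
        if not self.side_effect_terms:
            raise SchemaValidationError("at least one side-effect term is required")


@dataclass
class GroundTruthManifest:
    """Exact expected outputs of every inference algorithm on the fixture."""

    seed: int
    triple_count: int = 0
    drug_id: str = ""
    polypharmacology_hits: list = field(default_factory=list)
    polypharmacology_hits_with_nondruglike: list = field(default_factory=list)
    pathway_filter: str = ""
    pathway_inhibitor_hits: list = field(default_factory=list)
    multiply_inhibited_pathway_ids: list = field(default_factory=list)
    side_effect_terms: list = field(default_factory=list)
    side_effect_associations: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthManifest":
        return cls(**json.loads(text))


class _Builder:
    def __init__(self, schema: SchemaGraph):
        self.schema = schema
        self.graph = Graph()

    def node(self, class_name: str, local) -> URIRef:
        uri = URIRef(self.schema.mint_uri(class_name, local))
        self.graph.add((uri, RDF.type, URIRef(self.schema.get_class(class_name).type_uri)))
        return uri

    def compound(self, cid: int, mw: float, logp: float, hbd: int, hba: int,
                 smiles: str | None = None) -> URIRef:
        c = self.node("compound", cid)
        self.graph.add((c, VOCAB.mw, Literal(round(mw, 2))))
        self.graph.add((c, VOCAB.logp, Literal(round(logp, 2))))
        self.graph.add((c, VOCAB.hbd, Literal(hbd)))
        self.graph.add((c, VOCAB.hba, Literal(hba)))
        if smiles:
            self.graph.add((c, VOCAB.smiles, Literal(smiles)))
        return c

    def activity(self, assay_id: int, cid: int, target: str, outcome: int, score: int,
                 suffix: str = "") -> URIRef:
        rec = self.node("pubchem_bioassay", f"{assay_id}_{cid}{suffix}")
        self.graph.add((rec, VOCAB.assay_id, Literal(assay_id)))
        self.graph.add((rec, VOCAB.compound, URIRef(self.schema.mint_uri("compound", cid))))
        self.graph.add((rec, VOCAB.uniprot, URIRef(self.schema.mint_uri("uniprot", target))))
        self.graph.add((rec, VOCAB.outcome, Literal(outcome)))
        self.graph.add((rec, VOCAB.score, Literal(score)))
        return rec

    def drug_target(self, drug_id: str, target: str) -> URIRef:
        rec = self.node("drugbank_interaction", f"{drug_id}_{target}")
        self.graph.add((rec, VOCAB.drug, URIRef(self.schema.mint_uri("drugbank_drug", drug_id))))
        self.graph.add((rec, VOCAB.uniprot, URIRef(self.schema.mint_uri("uniprot", target))))
        return rec

    def membership(self, source: str, pathway_id: str, pathway_name: str, target: str) -> URIRef:
        rec = self.node(source, f"{pathway_id}_{target}")
        self.graph.add((rec, VOCAB.uniprot, URIRef(self.schema.mint_uri("uniprot", target))))
        self.graph.add((rec, VOCAB.pathway_id, Literal(pathway_id)))
        self.graph.add((rec, VOCAB.pathway_name, Literal(pathway_name)))
        return rec

    def side_effect(self, drug_id: str, term: str, idx: int) -> URIRef:
        rec = self.node("sider", f"{drug_id}_{idx}")
        self.graph.add((rec, VOCAB.drug, URIRef(self.schema.mint_uri("drugbank_drug", drug_id))))
        self.graph.add((rec, VOCAB.side_effect, Literal(term)))
        return rec

    def chem_link(self, source: str, idx: int, cid: int, target: str) -> URIRef:
        rec = self.node(source, f"{source}_{idx}")
        self.graph.add((rec, VOCAB.compound, URIRef(self.schema.mint_uri("compound", cid))))
        self.graph.add((rec, VOCAB.uniprot, URIRef(self.schema.mint_uri("uniprot", target))))
        return rec

    def ppi(self, source: str, idx: int, a: str, b: str) -> URIRef:
        rec = self.node(source, f"ppi{idx}")
        self.graph.add((rec, VOCAB.protein_a, URIRef(self.schema.mint_uri("uniprot", a))))
        self.graph.add((rec, VOCAB.protein_b, URIRef(self.schema.mint_uri("uniprot", b))))
        return rec


def _druglike(rng: random.Random) -> tuple[float, float, int, int]:
    return (rng.uniform(180, 480), rng.uniform(-1, 4.5), rng.randint(0, 4), rng.randint(1, 8))


def build_graph(spec: FixtureSpec, schema: SchemaGraph | None = None
                ) -> tuple[Graph, GroundTruthManifest]:
    """Build the fixture RDF graph and its ground-truth manifest."""
    spec.validate()
    schema = schema or default_schema()
    rng = random.Random(spec.seed)
    b = _Builder(schema)
    manifest = GroundTruthManifest(seed=spec.seed)

    # --- identifier pools (disjoint, seed-dependent) ---------------------
    n_targets = 9 + spec.n_noise_targets
    accession_pool = [f"P{n:05d}" for n in rng.sample(range(1, 90000), n_targets)]
    t1, t2, t3, t4, t5, t6, g1, g2, g3 = accession_pool[:9]
    noise_targets = accession_pool[9:]
    for acc in accession_pool:
        b.node("uniprot", acc)

    cid_pool = rng.sample(range(1000, 9_000_000), 10 + spec.n_noise_compounds)
    (drug_cid, hit2_cid, hit1_cid, fat_cid, low_cid, out1_cid, single_cid,
     pw_cid, pw_single_cid, pw_dup_cid) = cid_pool[:10]
    noise_cids = cid_pool[10:]

    drug_ids = [f"DB{n:05d}" for n in rng.sample(range(1, 90000), 5 + spec.n_noise_drugs)]
    drug_id, d1, d2, d3, d4 = drug_ids[:5]
    noise_drugs = drug_ids[5:]

    assay_ids = iter(rng.sample(range(100, 99999), 400))
    pathway_nums = rng.sample(range(10000, 99999), 4)
    mapk_pid, calcium_pid, apoptosis_pid = (f"hsa{n}" for n in pathway_nums[:3])
    reactome_pid = f"R-HSA-{pathway_nums[3]}"

    # --- case 1: polypharmacology around the reference drug --------------
    drug_uri = b.node("drugbank_drug", drug_id)
    b.graph.add((drug_uri, VOCAB.compound, URIRef(schema.mint_uri("compound", drug_cid))))
    for t in (t1, t2, t3):
        b.drug_target(drug_id, t)

    smiles = list(_SMILES_POOL)

    def score_hi() -> int:
        return rng.randint(60, 100)

    # the drug's own compound is active on two of its targets: must be excluded
    b.compound(drug_cid, *_druglike(rng), smiles=smiles[0])
    for t in (t1, t2):
        b.activity(next(assay_ids), drug_cid, t, 2, score_hi())

    # planted hit sharing 3 targets, with two assay records on the first
    b.compound(hit2_cid, *_druglike(rng), smiles=smiles[1])
    b.activity(next(assay_ids), hit2_cid, t1, 2, score_hi())
    b.activity(next(assay_ids), hit2_cid, t1, 2, score_hi())
    b.activity(next(assay_ids), hit2_cid, t2, 2, score_hi())
    b.activity(next(assay_ids), hit2_cid, t3, 2, score_hi())

    # planted hit sharing 2 targets
    b.compound(hit1_cid, *_druglike(rng), smiles=smiles[2])
    b.activity(next(assay_ids), hit1_cid, t1, 2, score_hi())
    b.activity(next(assay_ids), hit1_cid, t2, 2, score_hi())

    # decoys: each fails exactly one filter
    b.compound(fat_cid, rng.uniform(600, 800), 2.0, 2, 4)  # non-drug-like MW
    b.activity(next(assay_ids), fat_cid, t1, 2, score_hi())
    b.activity(next(assay_ids), fat_cid, t2, 2, score_hi())

    b.compound(low_cid, *_druglike(rng))  # score at or below threshold
    b.activity(next(assay_ids), low_cid, t1, 2, rng.randint(5, 50))
    b.activity(next(assay_ids), low_cid, t2, 2, rng.randint(5, 50))

    b.compound(out1_cid, *_druglike(rng))  # outcome 1 (inactive)
    b.activity(next(assay_ids), out1_cid, t1, 1, score_hi())
    b.activity(next(assay_ids), out1_cid, t2, 1, score_hi())

    b.compound(single_cid, *_druglike(rng))  # only one shared target
    b.activity(next(assay_ids), single_cid, t1, 2, score_hi())

    hit2 = {
        "cid": hit2_cid,
        "shared_targets": sorted([t1, t2, t3]),
        "path_count": 4,
        "druglike": True,
    }
    hit1 = {
        "cid": hit1_cid,
        "shared_targets": sorted([t1, t2]),
        "path_count": 2,
        "druglike": True,
    }
    fat = {
        "cid": fat_cid,
        "shared_targets": sorted([t1, t2]),
        "path_count": 2,
        "druglike": False,
    }
    manifest.drug_id = drug_id
    manifest.polypharmacology_hits = [hit2, hit1]
    manifest.polypharmacology_hits_with_nondruglike = sorted(
        [hit2, hit1, fat], key=lambda h: (-len(h["shared_targets"]), h["cid"])
    )

    # --- case 2: multi-target inhibition of one pathway -------------------
    name = f"{spec.pathway_filter} signalling pathway"
    for t in (t4, t5, t6):
        b.membership("kegg_pathway_protein", mapk_pid, name, t)
    b.membership("kegg_pathway_protein", calcium_pid, "Calcium signalling pathway", t1)
    b.membership("kegg_pathway_protein", calcium_pid, "Calcium signalling pathway", g3)

    b.compound(pw_cid, *_druglike(rng), smiles=smiles[3])
    b.activity(next(assay_ids), pw_cid, t4, 2, score_hi())
    b.activity(next(assay_ids), pw_cid, t5, 2, score_hi())

    b.compound(pw_single_cid, *_druglike(rng))  # one pathway target only
    b.activity(next(assay_ids), pw_single_cid, t4, 2, score_hi())

    b.compound(pw_dup_cid, *_druglike(rng))  # two assays, one distinct target
    b.activity(next(assay_ids), pw_dup_cid, t5, 2, score_hi())
    b.activity(next(assay_ids), pw_dup_cid, t5, 2, score_hi(), suffix="b")

    manifest.pathway_filter = spec.pathway_filter
    manifest.pathway_inhibitor_hits = [
        {"cid": pw_cid, "pathway_id": mapk_pid, "targets": sorted([t4, t5])}
    ]
    manifest.multiply_inhibited_pathway_ids = [mapk_pid]

    # --- case 3: side-effect -> pathway association ------------------------
    term = spec.side_effect_terms[0]
    for i, d in enumerate((d1, d2, d3, d4)):
        du = b.node("drugbank_drug", d)
        d_cid = noise_cids[i % len(noise_cids)]
        b.graph.add((du, VOCAB.compound, URIRef(schema.mint_uri("compound", d_cid))))
        b.side_effect(d, term, 0)
    for d in (d1, d2):
        b.drug_target(d, g1)
    for d in (d3, d4):
        b.drug_target(d, g2)
    b.drug_target(d1, g3)  # decoy: g3 has only one matching drug

    b.membership("kegg_pathway_protein", apoptosis_pid, "Apoptosis", g1)
    b.membership("kegg_pathway_protein", apoptosis_pid, "Apoptosis", g2)
    b.membership("reactome", reactome_pid, "Hemostasis", g1)  # one efficient gene

    manifest.side_effect_terms = sorted(spec.side_effect_terms)
    manifest.side_effect_associations = [
        {
            "pathway_id": apoptosis_pid,
            "efficient_genes": sorted([g1, g2]),
            "path_count": 4,
        }
    ]

    # --- noise (never creates a hit: activity noise is outcome 1, noise
    # side-effect terms never match the planted ones) ----------------------
    for cid in noise_cids:
        b.compound(cid, *_druglike(rng))
        b.activity(next(assay_ids), cid, rng.choice(noise_targets), 1, rng.randint(0, 100))
    for i, d in enumerate(noise_drugs):
        b.node("drugbank_drug", d)
        b.side_effect(d, rng.choice(_NOISE_SIDE_EFFECTS), 0)
        b.drug_target(d, rng.choice([g1, g2] + noise_targets))
    for source in ("ctd_interaction", "bindingdb_interaction", "matador", "qsar"):
        for i in range(spec.n_chem_records_per_source):
            b.chem_link(source, i, rng.choice(noise_cids), rng.choice(accession_pool))
    for source in ("hprd", "dip"):
        for i in range(spec.n_ppi_records_per_source):
            a, c = rng.sample(accession_pool, 2)
            b.ppi(source, i, a, c)
    for i, cid in enumerate(noise_cids[:2]):
        rec = b.node("pubmed2compound", f"pm{i}")
        b.graph.add((rec, VOCAB.compound, URIRef(schema.mint_uri("compound", cid))))

    manifest.triple_count = len(b.graph)
    return b.graph, manifest


def build_store(spec: FixtureSpec, schema: SchemaGraph | None = None
                ) -> tuple[TripleStore, GroundTruthManifest]:
    """In-memory fixture: a loaded store plus its manifest."""
    graph, manifest = build_graph(spec, schema)
    store = TripleStore()
    for triple in graph:
        store.add(triple)
    return store, manifest


def _nt_lines(graph: Graph) -> list[str]:
    return sorted(
        f"{s.n3()} {p.n3()} {o.n3()} ." for s, p, o in graph
    )


def generate(spec: FixtureSpec, out_dir) -> tuple[list[Path], GroundTruthManifest]:
    """Write the fixture as sorted N-Triples plus a JSON manifest.

    Output is a deterministic function of the spec: the same seed produces
    byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    graph, manifest = build_graph(spec)
    nt_path = out / "fixture.nt"
    nt_path.write_text("\n".join(_nt_lines(graph)) + "\n")
    manifest_path = out / "manifest.json"
    manifest_path.write_text(manifest.to_json() + "\n")
    return [nt_path, manifest_path], manifest
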