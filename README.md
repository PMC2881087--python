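# chemlink

Linked-path SPARQL generation and cross-source inference over chemogenomics
RDF graphs.

Modern drug discovery increasingly asks questions that no single database can
answer: does a screening compound share the *target profile* of a marketed
drug (polypharmacology)? Can one compound inhibit a pathway at two branch
points at once? Which pathways are statistically tied to an adverse drug
reaction? Answering them requires joining compounds, bioassay outcomes,
protein targets, drugs, pathways, and side-effect reports across
heterogeneous sources on shared identifiers (PubChem CID for chemicals,
UniProt accession for proteins).

chemlink is a self-contained engine for this kind of semantic systems
chemical biology. It provides:

* a **schema graph** of data-source classes connected by join-key edges,
  loaded from a declarative YAML config (a default schema ships with the
  package);
* a **linked-path generator** that enumerates every simple chain between an
  origin and a terminal class and compiles any chain into an executable
  SPARQL SELECT, with identifier, numeric, and term filters;
* an in-memory **RDF store** (rdflib) with deterministic query execution and
  InChI-key → CID identifier resolution;
* **cheminformatics SPARQL extensions**: 166-key MACCS fingerprints
  (RDKit backend, pluggable), Tanimoto similarity
  `T(A,B) = N_C / (N_A + N_B − N_C)`, Lipinski rule-of-five drug-likeness
  (MW ≤ 500, logP ≤ 5, HBD ≤ 5, HBA ≤ 10), and bioassay activity gating
  (outcome = 2 and score > 50);
* the three **cross-source inference analyses**: polypharmacology search
  (compounds sharing ≥ 2 active targets with a drug), multi-target pathway
  inhibition (compounds active on ≥ 2 distinct proteins of one pathway), and
  side-effect → pathway association via *efficient genes* (genes targeted by
  ≥ 2 drugs reporting the same side effect);
* **source-integration statistics**: per-source unique-record contribution
  percentages for homogeneous sources (PPI, pathway, chemogenomics) and the
  multi-source drug → gene → pathway linkage experiment;
* a **fixture generator** producing small synthetic RDF datasets with
  planted, manifest-declared ground truth, so the entire pipeline is testable
  without any external download.

## Worked example

Generate a fixture, then ask the three questions. The fixture plants a
reference drug with three protein targets, compounds with known activity
profiles, a pathway with two inhibited branch targets, and a side-effect
scenario; `manifest.json` declares the expected answers.

```sh
$ chemlink fixtures generate --seed 11 --out demo
$ chemlink case polypharm --data demo/fixture.nt --drug DB65507
cid     n_shared  shared_targets           path_count  druglike
2379927 3         P59295,P61034,P73371     4           True
1522199 2         P59295,P73371            2           True
```

Compound 2379927 is active (outcome 2, score > 50) against all three of the
drug's targets — via four evidence chains, because one target was confirmed
in two independent assays — and passes all four drug-likeness rules; compound
1522199 shares two targets. Decoys failing exactly one filter (low score,
inactive outcome, a single shared target, molecular weight 700) are absent.

```sh
$ chemlink case pathway-inhibitors --data demo/fixture.nt --pathway-name MAPK
cid     pathway_id  pathway_name              targets
252670  hsa36855    MAPK signalling pathway   P59223,P66564

$ chemlink case side-effect --data demo/fixture.nt --terms hepatitis
pathway_id  pathway_name  n_efficient_genes  efficient_genes   path_count
hsa94097    Apoptosis     2                  P24204,P24891     4
```

The pathway association is supported by four drug → gene → pathway chains:
two drugs reporting hepatitis target each of the two efficient genes, and
both genes sit in the same pathway.

Chemical similarity from the command line (MACCS/Tanimoto):

```sh
$ chemlink sim --query "CC(=O)Oc1ccccc1C(=O)O" --against "O=C(O)c1ccccc1O" --against "CCO"
smiles            tanimoto
O=C(O)c1ccccc1O   0.7391
CCO               0.1538
```

The same functions are registered as SPARQL extension functions, so a query
can filter directly on similarity or drug-likeness:

```sparql
SELECT ?c WHERE {
  ?c <http://example.org/chemlink/vocab#smiles> ?s .
  FILTER(<http://example.org/chemlink/fn#tanimoto>(?s, "CCO") > 0.8)
}
```

Library use mirrors the CLI:

```python
from chemlink import default_schema, enumerate_paths, path_to_sparql

schema = default_schema()
for path in enumerate_paths(schema, "compound", "drugbank_drug", max_length=4):
    print(path.length, path.classes)
```

See `docs/methods.md` for the model, thresholds, and the fixture design.

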