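# Methods

## The model

chemlink treats an integrated chemogenomics resource as two coupled graphs.

The **schema graph** is a typed multigraph whose nodes are entity classes —
one per data-source table (compounds, drugs, proteins, bioassay activity
records, drug–target interaction records, pathway-membership records,
side-effect records, PPI records, literature co-mentions) — and whose edges
are *join edges*: RDF object properties annotated with the identifier domain
shared by their two ends (PubChem CID for compounds, UniProt accession for
proteins, DrugBank accession for drugs, and so on). Classes carry one of six
source categories (chemical & drug, protein & gene, chemogenomics, systems,
phenotype, literature). Edges are stored directed, as asserted in RDF, but
traversed undirected: a drug's target link and an assay's target link meet
at the same protein regardless of assertion direction. Validation requires
that every edge pointing into a class joins on that class's own identifier
domain; edges leaving a class join on the node URI itself, so instance-level
joins are always well defined.

The **instance graph** is an ordinary RDF dataset conforming to the schema.
Record-style classes (activity rows, interaction rows, membership rows)
follow the relational-to-RDF convention: each row is a resource typed with
its class URI, holding object properties to the entities it joins and
datatype properties for its attributes (outcome, score, pathway id and name,
side-effect term, molecular descriptors). Outcome and score are typed
numeric literals so SPARQL comparisons are numeric, not lexical.

A **linked path** is a simple chain of classes connected by join edges.
Enumeration is a depth-first search over the undirected schema multigraph,
bounded by `max_length` (default 4 — the longest chain the analyses need,
side-effect → drug → target → pathway, has 3–4 hops, and unbounded
enumeration on a cyclic schema explodes). Parallel edges (distinct
predicates between one class pair) yield distinct paths. Results are ordered
by length, then lexicographically by the (class, predicate) label sequence,
so enumeration is deterministic. An origin equal to the terminal yields the
single zero-length path, which compilation rejects explicitly.

Compilation to SPARQL maps path position *i* to variable `?v{i}` and each
edge to exactly one triple pattern oriented as asserted. Constraints are
rendered as FILTER clauses: identifier pinning (`?v0 = <uri>`), numeric
comparisons on datatype properties (each property gets a dedicated `?p{j}`
variable bound by one extra pattern), and case-insensitive term membership
(`LCASE(STR(?p)) IN (...)`). Generation is a pure function of its inputs:
identical path and constraints produce byte-identical text.

## Cheminformatics functions

* **fingerprint(SMILES) → 166-bit vector.** The default backend computes the
  standard 166 MACCS structural keys with RDKit (RDKit's 167-slot vector has
  an unused slot 0; slots 1–166 are taken). The backend is pluggable — a
  table-driven backend serves tests and pipelines that need determinism
  without a chemistry engine. Key-level bit agreement across engines is not
  promised; the contracts are length, determinism, and the Tanimoto
  arithmetic.
* **tanimoto(A, B) = N_C / (N_A + N_B − N_C)** with N_C the shared set-bit
  count. Two all-zero fingerprints return 0 (no shared evidence) rather than
  raising on the zero denominator.
* **rule_of_five**: MW ≤ 500 Da, logP ≤ 5, H-bond donors ≤ 5, acceptors
  ≤ 10, boundaries inclusive; the overall pass is the conjunction of all
  four. Per-rule verdicts are returned.
* **is_active**: outcome code 2 (active) and normalized score strictly
  greater than the threshold (default 50, on the 0–100 scale).

All three are also registered as SPARQL extension functions under the
package function namespace, so queries can filter on similarity or
drug-likeness directly (`FILTER(fn:tanimoto(?smiles, "CCO") > 0.8)`).

## The three inference analyses

**Polypharmacology.** For a reference drug: collect its targets; join to
bioassay records on those targets via UniProt; keep active records
(outcome 2, score > threshold); optionally keep only rule-of-five passes
(compounds without descriptor triples are conservatively treated as not
drug-like); group evidence chains per compound and keep compounds with at
least `min_shared` (default 2) *distinct* shared targets. The drug's own
compound is excluded. Hits are ordered by descending shared-target count,
then CID. Distinct targets gate the hit; the raw chain count (one per
distinct full instance binding) is reported for ranking, so two assays on
one target raise the chain count but not the target count.

**Multi-target pathway inhibition.** The linking rule — compound *x* targets
protein *y*, *y* belongs to pathway *z*, therefore *x* relates to *z* — is
materialized as chains at assay-record granularity (no deduplication across
assays, and a protein in two pathways yields two chains per record). The
pathway search restricts chains to pathways whose name contains the filter
(case-insensitive substring, so "MAPK" matches "MAPK signalling pathway"),
groups by (compound, pathway), and keeps groups with at least `min_targets`
(default 2) distinct proteins. The census variant iterates every pathway and
counts those where at least one compound clears the same bar.

**Side-effect → pathway association.** Drugs are matched by case-insensitive
*exact* term equality against their side-effect records (the hepatotoxicity
use case lists discrete terms — necrosis, hepatitis, hepatomegaly — rather
than free text). A gene is *efficient* when at least `min_drugs_per_gene`
(default 2) matching drugs target it. A pathway containing at least
`min_genes_per_pathway` (default 2) efficient genes is associated, ranked by
the number of distinct drug → gene → pathway chains (more associative paths,
stronger evidence), tie-broken by efficient-gene count then pathway id, and
truncated to `top_k` (default 5).

All thresholds are parameters because the source phrasings are internally
inconsistent ("greater than 2" vs "at least two"); the defaults follow the
"at least two" reading throughout.

## Source-integration statistics

Records are canonicalized before set arithmetic: PPI pairs are unordered
(lexicographically sorted, self-interactions allowed), chemical–protein
interactions collapse to (CID, UniProt) regardless of assay provenance, and
pathway sources are measured both by the distinct proteins they involve and
by their distinct pathway records. Each source's contribution is
`100 × |source records| / |union|`, rounded half-up to one decimal
(`decimal.Decimal` quantization — banker's rounding would disagree on exact
ties). The linkage experiment counts distinct (drug CID, gene, pathway)
chains restricted to named source classes via their rdf:type provenance
tags; multiple records asserting the same chemical–gene link do not multiply
the count, so restricting sources is monotone in all three reported counts.

## Synthetic fixtures

The generator emits a schema-conformant instance graph in which every
algorithm's answer is planted and declared in a JSON manifest: a reference
drug with three targets; hits sharing two and three of them (one via a
duplicated assay, so chain count exceeds target count); decoys each failing
exactly one filter (score ≤ 50, outcome 1, a single shared target, MW
600–800); a pathway with two inhibited branch targets plus single-target and
duplicate-assay decoys; and a side-effect scenario with two efficient genes
in one pathway plus a one-drug gene and a one-gene pathway as decoys. Noise
activity records are always outcome 1 and noise side-effect terms never
match the planted ones, so noise cannot create hits by construction — which
is what makes exact planted-set recovery a meaningful test. Identifiers and
scores are drawn from a seeded RNG: the same seed is byte-identical, and
different seeds vary every identifier and score without moving the ground
truth.

What the fixtures do **not** emulate: realistic activity-score or
degree distributions, correlated assay panels, structure-derived
descriptors (descriptor values are sampled inside/outside the Lipinski
bounds by plant design), or database scale. Passing tests therefore
demonstrate algorithmic correctness of the joins, filters, grouping and
ranking — not robustness to the noise patterns of real chemogenomics data.
Default scale is a few hundred triples; the full suite runs in seconds.

## Numerical and engineering choices

* Percentages use exact rational arithmetic (`Decimal`) before half-up
  quantization; no floating-point rounding is involved.
* Query results are sorted by the string form of the selected variables, so
  repeated execution is bit-identical.
* Typed path queries express class constraints as `FILTER EXISTS` clauses
  rather than triple patterns: a greedy BGP evaluator schedules
  single-variable type patterns first and cross-products every typed
  instance before the join (three orders of magnitude slower on even small
  stores). As per-solution checks they are applied after the chain join.
* Tanimoto on two empty fingerprints is 0 by definition; fingerprint length
  is validated at construction (166), making dimension mismatches
  unrepresentable downstream.
* The drug-likeness boundaries are inclusive; activity uses a strict
  inequality on the score. Both follow the source conventions exactly.

## Known limitations

* The in-memory store is desk-scale; there is no indexing, persistence, or
  HTTP endpoint, and no owl:sameAs federation to external linked-data
  resources.
* Schema-level (not instance-level) paths are enumerated; instance bindings
  appear only when a compiled query is executed.
* Protein-sequence similarity search and OWL reasoning are out of scope.
* The published biological result sets (specific compounds and pathways)
  depend on 2010-era database snapshots and are not reproducible here; the
  algorithms are validated against planted fixtures instead.
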