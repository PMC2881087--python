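# Default chemogenomics schema bundled with chemlink.
#
# Classes are data-source tables; edges are the RDF object properties that
# join them, annotated with the identifier domain of the referenced end.
# Record-style classes (bioassay activity rows, drug-target interaction rows,
# pathway-membership rows, side-effect rows, PPI rows) carry their outcome /
# score / pathway / term attributes as datatype properties, which are not
# schema edges.
classes:
  - name: compound
    category: chemical_drug
    uri_prefix: http://example.org/chemlink/resource/compound/
  - name: drugbank_drug
    category: chemical_drug
    uri_prefix: http://example.org/chemlink/resource/drugbank_drug/
  - name: uniprot
    category: protein_gene
    uri_prefix: http://example.org/chemlink/resource/uniprot/
  - name: pubchem_bioassay
    category: chemogenomics
    uri_prefix: http://example.org/chemlink/resource/pubchem_bioassay/
  - name: drugbank_interaction
    category: chemogenomics
    uri_prefix: http://example.org/chemlink/resource/drugbank_interaction/
  - name: ctd_interaction
    category: chemogenomics
    uri_prefix: http://example.org/chemlink/resource/ctd_interaction/
  - name: bindingdb_interaction
    category: chemogenomics
    uri_prefix: http://example.org/chemlink/resource/bindingdb_interaction/
  - name: matador
    category: chemogenomics
    uri_prefix: http://example.org/chemlink/resource/matador/
  - name: qsar
    category: chemogenomics
    uri_prefix: http://example.org/chemlink/resource/qsar/
  - name: kegg_pathway_protein
    category: systems
    uri_prefix: http://example.org/chemlink/resource/kegg_pathway_protein/
  - name: reactome
    category: systems
    uri_prefix: http://example.org/chemlink/resource/reactome/
  - name: hprd
    category: systems
    uri_prefix: http://example.org/chemlink/resource/hprd/
  - name: dip
    category: systems
    uri_prefix: http://example.org/chemlink/resource/dip/
  - name: sider
    category: phenotype
    uri_prefix: http://example.org/chemlink/resource/sider/
  - name: pubmed2compound
    category: literature
    uri_prefix: http://example.org/chemlink/resource/pubmed2compound/

edges:
  # bioassay activity records join compounds (CID) to proteins (UniProt)
  - source: pubchem_bioassay
    target: compound
    predicate: http://example.org/chemlink/vocab#compound
    join_key: CID
  - source: pubchem_bioassay
    target: uniprot
    predicate: http://example.org/chemlink/vocab#uniprot
    join_key: UNIPROT_ACCESSION
  # drug-target interaction records
  - source: drugbank_interaction
    target: drugbank_drug
    predicate: http://example.org/chemlink/vocab#drug
    join_key: DRUG_ID
  - source: drugbank_interaction
    target: uniprot
    predicate: http://example.org/chemlink/vocab#uniprot
    join_key: UNIPROT_ACCESSION
  # a drug's structure is mapped to its PubChem compound
  - source: drugbank_drug
    target: compound
    predicate: http://example.org/chemlink/vocab#compound
    join_key: CID
  # other chemogenomics sources: chemical-protein interaction rows
  - source: ctd_interaction
    target: compound
    predicate: http://example.org/chemlink/vocab#compound
    join_key: CID
  - source: ctd_interaction
    target: uniprot
    predicate: http://example.org/chemlink/vocab#uniprot
    join_key: UNIPROT_ACCESSION
  - source: bindingdb_interaction
    target: compound
    predicate: http://example.org/chemlink/vocab#compound
    join_key: CID
  - source: bindingdb_interaction
    target: uniprot
    predicate: http://example.org/chemlink/vocab#uniprot
    join_key: UNIPROT_ACCESSION
  - source: matador
    target: compound
    predicate: http://example.org/chemlink/vocab#compound
    join_key: CID
  - source: matador
    target: uniprot
    predicate: http://example.org/chemlink/vocab#uniprot
    join_key: UNIPROT_ACCESSION
  - source: qsar
    target: compound
    predicate: http://example.org/chemlink/vocab#compound
    join_key: CID
  - source: qsar
    target: uniprot
    predicate: http://example.org/chemlink/vocab#uniprot
    join_key: UNIPROT_ACCESSION
  # pathway membership rows (one row per protein per pathway)
  - source: kegg_pathway_protein
    target: uniprot
    predicate: http://example.org/chemlink/vocab#uniprot
    join_key: UNIPROT_ACCESSION
  - source: reactome
    target: uniprot
    predicate: http://example.org/chemlink/vocab#uniprot
    join_key: UNIPROT_ACCESSION
  # protein-protein interaction rows (two parallel edges to uniprot)
  - source: hprd
    target: uniprot
    predicate: http://example.org/chemlink/vocab#protein_a
    join_key: UNIPROT_ACCESSION
  - source: hprd
    target: uniprot
    predicate: http://example.org/chemlink/vocab#protein_b
    join_key: UNIPROT_ACCESSION
  - source: dip
    target: uniprot
    predicate: http://example.org/chemlink/vocab#protein_a
    join_key: UNIPROT_ACCESSION
  - source: dip
    target: uniprot
    predicate: http://example.org/chemlink/vocab#protein_b
    join_key: UNIPROT_ACCESSION
  # side-effect rows attach terms to drugs
  - source: sider
    target: drugbank_drug
    predicate: http://example.org/chemlink/vocab#drug
    join_key: DRUG_ID
  # literature co-mentions
  - source: pubmed2compound
    target: compound
    predicate: http://example.org/chemlink/vocab#compound
    join_key: CID
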