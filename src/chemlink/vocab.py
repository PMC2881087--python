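"""URI conventions shared by the schema, the stores and the fixture generator.

Resources are minted as ``<base>/resource/<class>/<local-id>`` so every
instance URI carries its class and native identifier (CID for compounds,
UniProt accession for proteins, DrugBank accession for drugs).
"""

from rdflib import Namespace

BASE = "http://example.org/chemlink"

#: Prefix under which instance resources are minted.
RESOURCE = BASE + "/resource/"

#: Data and object properties (join predicates and record attributes).
VOCAB = Namespace(BASE + "/vocab#")

#: Class URIs used for rdf:type provenance tags on records.
CLASS = Namespace(BASE + "/class/")

#: Custom SPARQL extension functions (fingerprint, tanimoto, ruleOfFive).
FN = Namespace(BASE + "/fn#")


def class_uri(class_name: str) -> str:
    """URI identifying an entity class (used as the rdf:type of instances)."""
    return str(CLASS[class_name])


def local_id(uri: str) -> str:
    """Extract the local identifier from a minted resource URI."""
    return str(uri).rstrip("/").rsplit("/", 1)[-1]
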