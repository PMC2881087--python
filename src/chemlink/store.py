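"""In-memory RDF triple store with deterministic query execution.

Thin wrapper over :class:`rdflib.Graph`: loads N-Triples / Turtle / RDF-XML
files (set semantics, so reloading is idempotent), executes generated or raw
SPARQL with rows sorted by the selected variables, and resolves compound
identifiers (InChI key -> PubChem CID).
"""

from __future__ import annotations

import logging
import re
from typing import Iterable, Iterator, Mapping, Sequence, Union

from rdflib import Graph, Literal, URIRef

from .chem import register_sparql_functions
from .errors import IntegrityError, QueryError
from .paths import GeneratedQuery

logger = logging.getLogger("chemlink")

FORMATS = {"ntriples": "nt", "turtle": "turtle", "rdfxml": "xml"}


def _pythonize(term):
    if term is None:
        return None
    if isinstance(term, Literal):
        return term.toPython()
    return str(term)


class TripleStore:
    """A queryable set of RDF triples."""

    def __init__(self):
        self.graph = Graph()
        register_sparql_functions()

    # -- loading ----------------------------------------------------------

    @classmethod
    def load(cls, paths: Union[str, Sequence[str]], format: str = "ntriples") -> "TripleStore":
        store = cls()
        store.load_rdf(paths, format=format)
        return store

    def load_rdf(self, paths: Union[str, Sequence[str]], format: str = "ntriples") -> None:
        if format not in FORMATS:
            raise ValueError(
                f"unknown format {format!r}; expected one of {sorted(FORMATS)}"
            )
        if isinstance(paths, (str, bytes)) or hasattr(paths, "__fspath__"):
            paths = [paths]
        for path in paths:
            before = len(self.graph)
            try:
                self.graph.parse(str(path), format=FORMATS[format])
            except Exception as exc:
                raise QueryError(f"failed to parse {path}: {exc}") from exc
            logger.info("loaded %s: %d new triples", path, len(self.graph) - before)

    @property
    def size(self) -> int:
        return len(self.graph)

    def add(self, triple) -> None:
        self.graph.add(triple)

    def triples(self, pattern=(None, None, None)) -> Iterator:
        return self.graph.triples(pattern)

    def serialize(self, path, format: str = "ntriples") -> None:
        if format not in FORMATS:
            raise ValueError(f"unknown format {format!r}")
        self.graph.serialize(destination=str(path), format=FORMATS[format], encoding="utf-8")

    # -- querying ---------------------------------------------------------

    def execute(self, query: Union[str, GeneratedQuery]) -> list[dict[str, object]]:
        """Run a SELECT query; rows are dicts keyed by variable name, sorted
        by the string form of the selected variables so execution is pure."""
        text = query.text if isinstance(query, GeneratedQuery) else query
        try:
            result = self.graph.query(text)
        except Exception as exc:
            raise QueryError(f"query failed: {exc}") from exc
        vars_ = [str(v) for v in result.vars or []]
        rows = [
            {name: _pythonize(binding.get(name)) for name in vars_}
            for binding in result.bindings
        ]
        rows.sort(key=lambda row: tuple("" if row[v] is None else str(row[v]) for v in vars_))
        return rows

    # -- convenience accessors used by the inference layer ------------------

    def objects(self, subject: str, predicate: str) -> list:
        return sorted(
            (_pythonize(o) for o in self.graph.objects(URIRef(subject), URIRef(predicate))),
            key=str,
        )

    def subjects(self, predicate: str, obj) -> list[str]:
        term = obj if isinstance(obj, (URIRef, Literal)) else URIRef(obj)
        return sorted(str(s) for s in self.graph.subjects(URIRef(predicate), term))

    def sources_present(self) -> set[str]:
        """Local names of the rdf:type provenance tags present in the store."""
        from rdflib import RDF

        return {str(o).rsplit("/", 1)[-1] for o in self.graph.objects(None, RDF.type)}


# -- identifier normalization -------------------------------------------------

INCHI_KEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")


class IdentifierMappings:
    """InChI-key -> CID mapping set with uniqueness enforcement."""

    def __init__(self, pairs: Iterable[tuple[str, int]] = ()):
        self._map: dict[str, int] = {}
        for key, cid in pairs:
            self.add(key, cid)

    def add(self, inchi_key: str, cid: int) -> None:
        if not INCHI_KEY_RE.match(inchi_key):
            raise ValueError(f"malformed InChI key: {inchi_key!r}")
        if cid <= 0:
            raise ValueError("CID must be a positive integer")
        existing = self._map.get(inchi_key)
        if existing is not None and existing != cid:
            raise IntegrityError(
                f"InChI key {inchi_key} maps to both CID {existing} and CID {cid}"
            )
        self._map[inchi_key] = cid

    def resolve_cid(self, inchi_key: str) -> int | None:
        """Return the CID for a key, or None when unmapped."""
        if not INCHI_KEY_RE.match(inchi_key):
            raise ValueError(f"malformed InChI key: {inchi_key!r}")
        return self._map.get(inchi_key)

    def __len__(self) -> int:
        return len(self._map)


def resolve_cid(mappings: IdentifierMappings, structure_key: str) -> int | None:
    """Functional form of :meth:`IdentifierMappings.resolve_cid`."""
    return mappings.resolve_cid(structure_key)
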