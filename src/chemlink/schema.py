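"""Schema graph: entity classes (data sources) joined by typed key edges.

The schema is a small typed multigraph. Nodes are *entity classes* — one per
data source table (compound, bioassay record, drug, protein, pathway
membership, side-effect record, ...). Edges are *join edges*: an RDF object
property whose subject is an instance of the source class and whose object is
an instance of the target class, annotated with the identifier domain the two
ends share (CID, UNIPROT_ACCESSION, DRUG_ID, ...). Edges are stored directed,
as they are asserted in RDF, but path enumeration treats them as undirected
because query chains may traverse a link in either orientation (a drug's
target and an assay's target meet at the same protein).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Iterator

import yaml

from .errors import SchemaParseError, SchemaValidationError, UnknownClassError
from .vocab import class_uri

#: The six source categories; every entity class belongs to exactly one.
CATEGORIES = frozenset(
    {
        "chemical_drug",
        "protein_gene",
        "chemogenomics",
        "systems",
        "phenotype",
        "literature",
    }
)


@dataclass(frozen=True)
class EntityClass:
    """A data-source class, e.g. ``compound`` or ``pubchem_bioassay``."""

    name: str
    category: str
    uri_prefix: str

    def __post_init__(self):
        if not self.name:
            raise SchemaValidationError("entity class name must be non-empty")
        if self.category not in CATEGORIES:
            raise SchemaValidationError(
                f"class {self.name!r}: unknown category {self.category!r} "
                f"(expected one of {sorted(CATEGORIES)})"
            )
        if not self.uri_prefix:
            raise SchemaValidationError(f"class {self.name!r}: empty uri_prefix")

    @property
    def type_uri(self) -> str:
        return class_uri(self.name)


@dataclass(frozen=True)
class JoinEdge:
    """A directed link between two classes via an RDF predicate.

    ``join_key`` names the identifier domain of the *target* end — the key on
    which the two classes join (e.g. CID when the edge points at ``compound``).
    """

    source_class: str
    target_class: str
    predicate: str
    join_key: str

    def __post_init__(self):
        if not self.predicate:
            raise SchemaValidationError(
                f"edge {self.source_class}->{self.target_class}: empty predicate"
            )

    def other_end(self, class_name: str) -> str:
        if class_name == self.source_class:
            return self.target_class
        if class_name == self.target_class:
            return self.source_class
        raise UnknownClassError(f"{class_name!r} is not an endpoint of {self}")


class SchemaGraph:
    """Validated collection of entity classes and join edges."""

    def __init__(self, classes: Iterable[EntityClass], edges: Iterable[JoinEdge]):
        self.classes: dict[str, EntityClass] = {}
        for cls in classes:
            if cls.name in self.classes:
                raise SchemaValidationError(f"duplicate class name {cls.name!r}")
            self.classes[cls.name] = cls
        self.edges: tuple[JoinEdge, ...] = tuple(edges)
        self._validate()

    # -- validation ------------------------------------------------------

    def _validate(self) -> None:
        for edge in self.edges:
            for endpoint in (edge.source_class, edge.target_class):
                if endpoint not in self.classes:
                    raise SchemaValidationError(
                        f"edge {edge.source_class!r}->{edge.target_class!r} "
                        f"references undeclared class {endpoint!r}"
                    )
        # All edges pointing INTO a class must join on that class's own
        # identifier domain; a mismatch means two sources disagree on how to
        # join at that class and instance-level joins would be meaningless.
        key_at: dict[str, str] = {}
        for edge in self.edges:
            seen = key_at.setdefault(edge.target_class, edge.join_key)
            if seen != edge.join_key:
                raise SchemaValidationError(
                    f"join-key mismatch at class {edge.target_class!r}: "
                    f"{seen!r} vs {edge.join_key!r}"
                )

    # -- queries ---------------------------------------------------------

    def __contains__(self, class_name: str) -> bool:
        return class_name in self.classes

    def get_class(self, class_name: str) -> EntityClass:
        try:
            return self.classes[class_name]
        except KeyError:
            raise UnknownClassError(f"unknown class {class_name!r}") from None

    def neighbors(self, class_name: str) -> list[tuple[JoinEdge, EntityClass]]:
        """All edges incident to ``class_name`` (either direction), each paired
        with the opposite endpoint, sorted by (predicate, neighbour name)."""
        self.get_class(class_name)
        out = []
        for edge in self.edges:
            if class_name in (edge.source_class, edge.target_class):
                other = self.get_class(edge.other_end(class_name))
                out.append((edge, other))
                # self-loop would need listing twice, but the validator has no
                # use case for one: skip the special case.
        out.sort(key=lambda pair: (pair[0].predicate, pair[1].name))
        return out

    def edges_between(self, a: str, b: str) -> list[JoinEdge]:
        """Edges joining classes ``a`` and ``b`` in either direction."""
        return [e for e, other in self.neighbors(a) if other.name == b]

    def mint_uri(self, class_name: str, local: str | int) -> str:
        prefix = self.get_class(class_name).uri_prefix
        if not prefix.endswith("/"):
            prefix += "/"
        return f"{prefix}{local}"

    def components(self) -> list[frozenset[str]]:
        """Connected components over the undirected view, largest first."""
        remaining = set(self.classes)
        comps = []
        while remaining:
            seed = min(remaining)
            comp, frontier = {seed}, [seed]
            while frontier:
                node = frontier.pop()
                for _, other in self.neighbors(node):
                    if other.name not in comp:
                        comp.add(other.name)
                        frontier.append(other.name)
            comps.append(frozenset(comp))
            remaining -= comp
        comps.sort(key=lambda c: (-len(c), min(c)))
        return comps

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "classes": [
                {"name": c.name, "category": c.category, "uri_prefix": c.uri_prefix}
                for c in self.classes.values()
            ],
            "edges": [
                {
                    "source": e.source_class,
                    "target": e.target_class,
                    "predicate": e.predicate,
                    "join_key": e.join_key,
                }
                for e in self.edges
            ],
        }

    def dumps(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.dumps())

    def __eq__(self, other) -> bool:
        if not isinstance(other, SchemaGraph):
            return NotImplemented
        return self.classes == other.classes and self.edges == other.edges

    def __repr__(self) -> str:
        return f"SchemaGraph({len(self.classes)} classes, {len(self.edges)} edges)"


def _parse(data: dict, origin: str) -> SchemaGraph:
    if not isinstance(data, dict):
        raise SchemaParseError(f"{origin}: top level must be a mapping")
    try:
        raw_classes = data["classes"]
        raw_edges = data.get("edges", [])
    except (KeyError, TypeError) as exc:
        raise SchemaParseError(f"{origin}: missing 'classes' block") from exc
    classes, edges = [], []
    for i, entry in enumerate(raw_classes):
        try:
            classes.append(
                EntityClass(entry["name"], entry["category"], entry["uri_prefix"])
            )
        except (KeyError, TypeError) as exc:
            raise SchemaParseError(f"{origin}: classes[{i}] is malformed: {entry!r}") from exc
    for i, entry in enumerate(raw_edges):
        try:
            edges.append(
                JoinEdge(entry["source"], entry["target"], entry["predicate"], entry["join_key"])
            )
        except (KeyError, TypeError) as exc:
            raise SchemaParseError(f"{origin}: edges[{i}] is malformed: {entry!r}") from exc
    return SchemaGraph(classes, edges)


def load_schema(config_path) -> SchemaGraph:
    """Load and validate a schema graph from a YAML config file."""
    with open(config_path) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise SchemaParseError(f"{config_path}: {exc}") from exc
    return _parse(data, str(config_path))


def loads_schema(text: str) -> SchemaGraph:
    """Load a schema graph from a YAML string."""
    try:
        data = yaml.safe_load(io.StringIO(text))
    except yaml.YAMLError as exc:
        raise SchemaParseError(str(exc)) from exc
    return _parse(data, "<string>")


def default_schema() -> SchemaGraph:
    """The schema bundled with the package, covering the data sources the
    inference algorithms and integration statistics operate over."""
    text = resources.files("chemlink.data").joinpath("default_schema.yaml").read_text()
    return loads_schema(text)
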