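"""Linked-path enumeration and compilation to SPARQL.

A *link path* is a simple chain of entity classes connected by join edges.
Given an origin and a terminal class, :func:`enumerate_paths` lists every
simple path up to a length bound (edges traversed undirected, parallel edges
kept distinct), and :func:`path_to_sparql` compiles a path into a SPARQL
SELECT whose triple patterns mirror the chain: position ``i`` of the path
becomes variable ``?v{i}``, and each join edge becomes exactly one triple
pattern oriented as asserted in RDF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

from .errors import PathCompilationError, QueryError, UnknownClassError
from .schema import JoinEdge, SchemaGraph


@dataclass(frozen=True)
class LinkPath:
    """A simple class chain: ``classes`` has length k+1, ``edges`` length k."""

    classes: tuple[str, ...]
    edges: tuple[JoinEdge, ...] = ()

    def __post_init__(self):
        if len(self.classes) != len(self.edges) + 1:
            raise ValueError("classes must be one longer than edges")
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("link paths are simple: no repeated class")
        for i, edge in enumerate(self.edges):
            ends = {edge.source_class, edge.target_class}
            if ends != {self.classes[i], self.classes[i + 1]}:
                raise ValueError(f"edge {i} does not connect positions {i},{i + 1}")

    @property
    def length(self) -> int:
        return len(self.edges)

    @property
    def origin(self) -> str:
        return self.classes[0]

    @property
    def terminal(self) -> str:
        return self.classes[-1]

    def sort_key(self):
        labels: list[str] = [self.classes[0]]
        for edge, cls in zip(self.edges, self.classes[1:]):
            labels.extend((edge.predicate, cls))
        return (self.length, tuple(labels))

    def __str__(self) -> str:
        parts = [self.classes[0]]
        for edge, cls in zip(self.edges, self.classes[1:]):
            arrow = "->" if edge.source_class == parts[-1].split("[")[0] else "<-"
            parts.append(f"{arrow}[{edge.predicate}] {cls}")
        return " ".join(parts)


def enumerate_paths(
    graph: SchemaGraph, origin: str, terminal: str, max_length: int = 4
) -> list[LinkPath]:
    """All simple paths of length <= ``max_length`` between two classes.

    Edges are traversed undirected; parallel edges (distinct predicates
    between the same pair) yield distinct paths. Results are ordered by
    ascending length, then lexicographically by the (class, predicate) label
    sequence. ``origin == terminal`` yields the single zero-length path.
    """
    graph.get_class(origin)
    graph.get_class(terminal)
    if max_length < 1:
        raise ValueError("max_length must be >= 1")
    if origin == terminal:
        return [LinkPath((origin,), ())]

    found: list[LinkPath] = []

    def dfs(node: str, classes: list[str], edges: list[JoinEdge]) -> None:
        if node == terminal:
            found.append(LinkPath(tuple(classes), tuple(edges)))
            return
        if len(edges) == max_length:
            return
        for edge, other in graph.neighbors(node):
            if other.name in classes:
                continue
            classes.append(other.name)
            edges.append(edge)
            dfs(other.name, classes, edges)
            classes.pop()
            edges.pop()

    dfs(origin, [origin], [])
    found.sort(key=LinkPath.sort_key)
    return found


def build_path(graph: SchemaGraph, class_names: Sequence[str],
               predicates: Sequence[str | None] | None = None) -> LinkPath:
    """Construct the link path through the given class sequence.

    When two classes are joined by parallel edges the predicate must be given
    to disambiguate; otherwise the unique edge is taken.
    """
    if predicates is None:
        predicates = [None] * (len(class_names) - 1)
    edges = []
    for i, (a, b) in enumerate(zip(class_names, class_names[1:])):
        candidates = graph.edges_between(a, b)
        if predicates[i] is not None:
            candidates = [e for e in candidates if e.predicate == predicates[i]]
        if not candidates:
            raise UnknownClassError(f"no edge between {a!r} and {b!r}")
        if len(candidates) > 1:
            raise PathCompilationError(
                f"ambiguous edge between {a!r} and {b!r}: specify a predicate"
            )
        edges.append(candidates[0])
    return LinkPath(tuple(class_names), tuple(edges))


# -- filters and projections ---------------------------------------------

_OPS = {"=", "!=", "<", ">", "<=", ">="}


@dataclass(frozen=True)
class IdentifierEquals:
    """Pin a path position to a specific resource URI."""

    class_name: str
    uri: str


@dataclass(frozen=True)
class PropertyFilter:
    """Numeric/equality constraint on a datatype property of one position."""

    class_name: str
    property_uri: str
    op: str
    value: Union[int, float, str]

    def __post_init__(self):
        if self.op not in _OPS:
            raise QueryError(f"unsupported operator {self.op!r}")


@dataclass(frozen=True)
class TermIn:
    """Case-insensitive term membership on a datatype property."""

    class_name: str
    property_uri: str
    terms: tuple[str, ...]


@dataclass(frozen=True)
class Projection:
    """Expose a datatype property of one position as a result column."""

    class_name: str
    property_uri: str


Constraint = Union[IdentifierEquals, PropertyFilter, TermIn]


@dataclass(frozen=True)
class GeneratedQuery:
    """A compiled SPARQL SELECT plus its variable layout."""

    text: str
    variables: Mapping[int, str]
    origin_var: str
    terminal_var: str
    property_vars: Mapping[tuple[str, str], str] = field(default_factory=dict)


def _sparql_literal(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    escaped = str(value).replace("\\", "\\\\").replace('"', '\\"')
    return f'"{escaped}"'


def path_to_sparql(
    path: LinkPath,
    filters: Iterable[Constraint] = (),
    projections: Iterable[Projection] = (),
    select_all: bool = False,
    typed: bool = False,
    graph: SchemaGraph | None = None,
) -> GeneratedQuery:
    """Compile a link path into a deterministic SPARQL SELECT.

    One triple pattern per edge, oriented as the edge is asserted; adjacent
    patterns share the variable of their common class. Filters become FILTER
    clauses; filter-referenced and projected properties get their own
    variables, bound by extra triple patterns. With ``typed=True`` an
    ``rdf:type`` pattern is added per position (``graph`` required), which
    disambiguates record classes that reuse the same join predicates.
    """
    if path.length < 1:
        raise PathCompilationError("cannot compile a zero-length path")
    pos_of = {name: i for i, name in enumerate(path.classes)}
    variables = {i: f"v{i}" for i in range(len(path.classes))}

    def var_for(class_name: str) -> str:
        if class_name not in pos_of:
            raise QueryError(f"class {class_name!r} is not on the path")
        return variables[pos_of[class_name]]

    patterns: list[str] = []
    for i, edge in enumerate(path.edges):
        if edge.source_class == path.classes[i]:
            s, o = variables[i], variables[i + 1]
        else:
            s, o = variables[i + 1], variables[i]
        patterns.append(f"?{s} <{edge.predicate}> ?{o} .")
    # Type constraints go in as FILTER EXISTS so they act as per-solution
    # checks on the joined chain; as plain single-variable triple patterns a
    # greedy evaluator schedules them first and cross-products every typed
    # instance before the join.
    type_clauses: list[str] = []
    if typed:
        if graph is None:
            raise QueryError("typed compilation requires the schema graph")
        for i, name in enumerate(path.classes):
            type_clauses.append(
                f"FILTER EXISTS {{ ?{variables[i]} a <{graph.get_class(name).type_uri}> }}"
            )

    # one property variable per distinct (class, property), in order of use
    property_vars: dict[tuple[str, str], str] = {}

    def prop_var(class_name: str, property_uri: str) -> str:
        key = (class_name, property_uri)
        if key not in property_vars:
            name = f"p{len(property_vars)}"
            property_vars[key] = name
            patterns.append(f"?{var_for(class_name)} <{property_uri}> ?{name} .")
        return property_vars[key]

    filter_clauses: list[str] = []
    filter_vars: list[str] = []
    for constraint in filters:
        if isinstance(constraint, IdentifierEquals):
            v = var_for(constraint.class_name)
            filter_clauses.append(f"FILTER (?{v} = <{constraint.uri}>)")
        elif isinstance(constraint, PropertyFilter):
            v = prop_var(constraint.class_name, constraint.property_uri)
            if v not in filter_vars:
                filter_vars.append(v)
            filter_clauses.append(
                f"FILTER (?{v} {constraint.op} {_sparql_literal(constraint.value)})"
            )
        elif isinstance(constraint, TermIn):
            v = prop_var(constraint.class_name, constraint.property_uri)
            if v not in filter_vars:
                filter_vars.append(v)
            terms = ", ".join(
                _sparql_literal(t.lower()) for t in sorted(constraint.terms)
            )
            filter_clauses.append(f"FILTER (LCASE(STR(?{v})) IN ({terms}))")
        else:
            raise QueryError(f"unsupported filter {constraint!r}")

    projected: list[str] = []
    for proj in projections:
        v = prop_var(proj.class_name, proj.property_uri)
        if v not in projected:
            projected.append(v)

    if select_all:
        select = [variables[i] for i in range(len(path.classes))]
    else:
        select = [variables[0], variables[len(path.classes) - 1]]
    for v in filter_vars + projected:
        if v not in select:
            select.append(v)

    lines = [f"SELECT {' '.join('?' + v for v in select)}", "WHERE {"]
    lines.extend(f"  {p}" for p in patterns)
    lines.extend(f"  {f}" for f in filter_clauses)
    lines.extend(f"  {c}" for c in type_clauses)
    lines.append("}")
    text = "\n".join(lines)
    return GeneratedQuery(
        text=text,
        variables=variables,
        origin_var=variables[0],
        terminal_var=variables[len(path.classes) - 1],
        property_vars=dict(property_vars),
    )


def group_paths_by_endpoint(
    bindings: Sequence[Mapping[str, object]],
    endpoint_var: str,
    min_paths: int = 2,
) -> dict[object, int]:
    """Count distinct evidence rows per endpoint value, keep counts >= min.

    The returned mapping is ordered by descending count, then by endpoint.
    """
    counts: dict[object, set] = {}
    for row in bindings:
        if endpoint_var not in row:
            raise QueryError(f"variable {endpoint_var!r} missing from bindings")
        key = row[endpoint_var]
        evidence = tuple(sorted((str(k), str(v)) for k, v in row.items()))
        counts.setdefault(key, set()).add(evidence)
    kept = {ep: len(rows) for ep, rows in counts.items() if len(rows) >= min_paths}
    ordered = sorted(kept.items(), key=lambda kv: (-kv[1], str(kv[0])))
    return dict(ordered)
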