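import random

import pytest

from chemlink.errors import PathCompilationError, QueryError, UnknownClassError
from chemlink.paths import (
    IdentifierEquals,
    LinkPath,
    PropertyFilter,
    build_path,
    enumerate_paths,
    group_paths_by_endpoint,
    path_to_sparql,
)
from chemlink.schema import EntityClass, JoinEdge, SchemaGraph
from chemlink.store import TripleStore

from .oracles import enumerate_paths_networkx, path_set


def mk_schema(names, edge_specs):
    classes = [EntityClass(n, "chemogenomics", f"http://x/{n}/") for n in names]
    edges = [JoinEdge(a, b, p, b.upper()) for a, b, p in edge_specs]
    return SchemaGraph(classes, edges)


@pytest.fixture()
def diamond():
    # two parallel routes compound -> ... -> drug, as in a two-evidence join
    return mk_schema(
        ["compound", "assay", "interaction", "target", "drug"],
        [
            ("assay", "compound", "http://x/p/compound"),
            ("assay", "target", "http://x/p/target"),
            ("interaction", "compound", "http://x/p/compound"),
            ("interaction", "target", "http://x/p/target"),
            ("interaction", "drug", "http://x/p/drug"),
            ("assay", "drug", "http://x/p/drug"),
        ],
    )


def test_two_node_graph_single_path():
    g = mk_schema(["a", "b"], [("a", "b", "http://x/p")])
    paths = enumerate_paths(g, "a", "b", 3)
    assert [p.classes for p in paths] == [("a", "b")]


def test_diamond_has_two_length4_routes(diamond):
    paths = enumerate_paths(diamond, "compound", "drug", 4)
    four_hop = [p for p in paths if p.length == 4]
    # compound-assay-target-interaction-drug and compound-interaction-target-assay-drug
    assert len(four_hop) == 2


def test_origin_equals_terminal_gives_zero_length_path(diamond):
    paths = enumerate_paths(diamond, "compound", "compound", 4)
    assert len(paths) == 1 and paths[0].length == 0


def test_max_length_cuts_long_paths():
    g = mk_schema(["a", "b", "c"], [("a", "b", "http://x/p1"), ("b", "c", "http://x/p2")])
    assert enumerate_paths(g, "a", "c", 1) == []


def test_unknown_class_raises(diamond):
    with pytest.raises(UnknownClassError):
        enumerate_paths(diamond, "compound", "nope", 4)


def test_parallel_edges_yield_distinct_paths():
    g = mk_schema(["a", "b"], [("a", "b", "http://x/p1"), ("a", "b", "http://x/p2")])
    paths = enumerate_paths(g, "a", "b", 2)
    assert len(paths) == 2
    assert [p.edges[0].predicate for p in paths] == ["http://x/p1", "http://x/p2"]


def test_ordering_is_length_then_lexicographic(diamond):
    paths = enumerate_paths(diamond, "compound", "drug", 4)
    keys = [p.sort_key() for p in paths]
    assert keys == sorted(keys)


def test_simple_path_invariant_and_bound_hold(diamond):
    for p in enumerate_paths(diamond, "compound", "drug", 4):
        assert len(set(p.classes)) == len(p.classes)
        assert p.length <= 4


def test_enumeration_matches_networkx_oracle_on_random_graphs():
    from .oracles import random_schema

    rng = random.Random(20240517)
    for _ in range(25):
        g = random_schema(rng)
        names = sorted(g.classes)
        origin, terminal = rng.choice(names), rng.choice(names)
        max_length = rng.randint(1, 5)
        ours = path_set(enumerate_paths(g, origin, terminal, max_length))
        theirs = enumerate_paths_networkx(g, origin, terminal, max_length)
        assert ours == theirs


# -- compilation ------------------------------------------------------------


def test_single_edge_path_compiles_to_one_pattern():
    g = mk_schema(["compound", "assay"], [("assay", "compound", "http://x/p/c")])
    q = path_to_sparql(build_path(g, ["compound", "assay"]))
    assert q.text.count("http://x/p/c") == 1
    assert q.origin_var == "v0" and q.terminal_var == "v1"
    # edge asserted assay->compound: compound is the object
    assert "?v1 <http://x/p/c> ?v0 ." in q.text


def test_compilation_is_deterministic(diamond):
    path = enumerate_paths(diamond, "compound", "drug", 4)[0]
    filters = [PropertyFilter("assay", "http://x/v#score", ">", 50)]
    assert path_to_sparql(path, filters).text == path_to_sparql(path, filters).text


def test_zero_length_path_rejected():
    with pytest.raises(PathCompilationError):
        path_to_sparql(LinkPath(("compound",), ()))


def test_every_edge_becomes_exactly_one_triple_pattern(diamond):
    for path in enumerate_paths(diamond, "compound", "drug", 4):
        q = path_to_sparql(path)
        patterns = [l for l in q.text.splitlines() if l.strip().startswith("?")]
        assert len(patterns) == path.length


def test_generated_query_executes_against_planted_chain():
    """Compile a 3-edge path with activity filters; run it on a hand-built
    store planting one compliant chain and one failing each filter."""
    g = mk_schema(
        ["compound", "assay", "target", "interaction", "drug"],
        [
            ("assay", "compound", "http://x/p/compound"),
            ("assay", "target", "http://x/p/target"),
            ("interaction", "target", "http://x/p/target"),
            ("interaction", "drug", "http://x/p/drug"),
        ],
    )
    path = build_path(g, ["compound", "assay", "target", "interaction", "drug"])
    q = path_to_sparql(
        path,
        filters=[
            PropertyFilter("assay", "http://x/v#outcome", "=", 2),
            PropertyFilter("assay", "http://x/v#score", ">", 50),
            IdentifierEquals("drug", "http://x/drug/D1"),
        ],
    )
    from rdflib import Literal, URIRef

    store = TripleStore()

    def chain(tag, outcome, score, drug="D1"):
        a, t, i = (URIRef(f"http://x/{k}/{tag}") for k in ("assay", "target", "interaction"))
        c = URIRef(f"http://x/compound/{tag}")
        store.add((a, URIRef("http://x/p/compound"), c))
        store.add((a, URIRef("http://x/p/target"), t))
        store.add((a, URIRef("http://x/v#outcome"), Literal(outcome)))
        store.add((a, URIRef("http://x/v#score"), Literal(score)))
        store.add((i, URIRef("http://x/p/target"), t))
        store.add((i, URIRef("http://x/p/drug"), URIRef(f"http://x/drug/{drug}")))

    chain("good", 2, 80)
    chain("inactive", 1, 80)
    chain("weak", 2, 50)
    chain("otherdrug", 2, 80, drug="D2")

    rows = store.execute(q)
    assert [row[q.origin_var] for row in rows] == ["http://x/compound/good"]


# -- endpoint grouping -------------------------------------------------------


def test_group_counts_distinct_rows_per_endpoint():
    rows = [
        {"c": "c1", "t": "t1"},
        {"c": "c1", "t": "t2"},
        {"c": "c2", "t": "t1"},
        {"c": "c1", "t": "t1"},  # duplicate evidence row: not double-counted
    ]
    assert group_paths_by_endpoint(rows, "c", 2) == {"c1": 2}


def test_group_empty_and_min_one():
    assert group_paths_by_endpoint([], "c", 2) == {}
    rows = [{"c": "c1"}, {"c": "c2"}]
    assert group_paths_by_endpoint(rows, "c", 1) == {"c1": 1, "c2": 1}


def test_group_missing_variable_is_an_error():
    with pytest.raises(QueryError, match="missing"):
        group_paths_by_endpoint([{"c": "c1"}], "zz", 1)
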