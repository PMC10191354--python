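"""Ontology graph: loading, ancestor queries, obsolete-id resolution.

`is_ancestor` is cross-checked against an independent transitive-closure
oracle computed by boolean matrix powers over random DAGs.
"""

import random

import numpy as np
import pytest

from phenokit.ontology import (
    OntologyGraph,
    OntologyLoadError,
    UnknownTermError,
    fixture_ontology_dict,
    load_ontology,
    make_fixture_ontology,
)


def closure_oracle(n_nodes: int, edges: list[tuple[int, int]]) -> np.ndarray:
    """Reachability by repeated boolean matrix multiplication."""
    adjacency = np.zeros((n_nodes, n_nodes), dtype=bool)
    for child, parent in edges:
        adjacency[child, parent] = True
    closure = adjacency.copy()
    for _ in range(n_nodes):
        updated = closure | (closure @ adjacency)
        if (updated == closure).all():
            break
        closure = updated
    return closure


def random_dag(rng: random.Random, n_nodes: int) -> list[tuple[int, int]]:
    # Edges only from higher to lower index: acyclic by construction.
    edges = []
    for child in range(1, n_nodes):
        for parent in rng.sample(range(child), k=min(child, rng.randrange(0, 3))):
            edges.append((child, parent))
    return edges


def graph_from_edges(n_nodes: int, edges) -> OntologyGraph:
    nodes = [{"id": f"T:{i:04d}", "lbl": f"term {i}"} for i in range(n_nodes)]
    edge_list = [
        {"sub": f"T:{c:04d}", "pred": "is_a", "obj": f"T:{p:04d}"} for c, p in edges
    ]
    return load_ontology({"graphs": [{"nodes": nodes, "edges": edge_list}]})


def test_fixture_contains_expected_hierarchy(graph):
    assert graph.is_ancestor("HP:0004942", "HP:0002616")  # aortic aneurysm over root aneurysm
    assert graph.is_ancestor("HP:0001167", "HP:0001166")  # finger over arachnodactyly
    assert graph.is_ancestor("HP:0000478", "HP:0001083")  # eye over ectopia lentis
    assert "HP:0004942" in graph.ancestors("HP:0002616")
    assert graph.labels["HP:0011463"] == "Childhood onset"


def test_strictness_a_term_is_not_its_own_ancestor(graph):
    for term in graph.terms:
        assert not graph.is_ancestor(term, term)
        assert term not in graph.ancestors(term)


def test_roots_have_no_ancestors(graph):
    for root in graph.roots:
        assert graph.ancestors(root) == set()


def test_primary_id_resolution(graph):
    assert graph.primary_id("HP:0002631") == "HP:0002616"
    assert graph.primary_id("HP:0004942") == "HP:0004942"
    assert graph.primary_of["HP:0002631"] not in graph.primary_of
    with pytest.raises(UnknownTermError):
        graph.primary_id("HP:9999999")


def test_cycle_detected_at_load():
    document = {
        "graphs": [
            {
                "nodes": [{"id": "A:1", "lbl": "a"}, {"id": "A:2", "lbl": "b"}],
                "edges": [
                    {"sub": "A:1", "pred": "is_a", "obj": "A:2"},
                    {"sub": "A:2", "pred": "is_a", "obj": "A:1"},
                ],
            }
        ]
    }
    with pytest.raises(OntologyLoadError):
        load_ontology(document)


def test_dangling_replacement_rejected():
    document = {
        "graphs": [
            {
                "nodes": [
                    {"id": "A:1", "lbl": "a"},
                    {
                        "id": "A:9",
                        "lbl": "obsolete",
                        "meta": {
                            "deprecated": True,
                            "basicPropertyValues": [
                                {"pred": "IAO:0100001", "val": "A:404"}
                            ],
                        },
                    },
                ],
                "edges": [],
            }
        ]
    }
    with pytest.raises(OntologyLoadError):
        load_ontology(document)


def test_iri_identifiers_normalized_to_curies():
    document = {
        "graphs": [
            {
                "nodes": [
                    {"id": "http://purl.obolibrary.org/obo/HP_0000001", "lbl": "All"},
                    {"id": "http://purl.obolibrary.org/obo/HP_0000002", "lbl": "x"},
                ],
                "edges": [
                    {
                        "sub": "http://purl.obolibrary.org/obo/HP_0000002",
                        "pred": "is_a",
                        "obj": "http://purl.obolibrary.org/obo/HP_0000001",
                    }
                ],
            }
        ]
    }
    graph = load_ontology(document)
    assert graph.is_ancestor("HP:0000001", "HP:0000002")


def test_non_is_a_edges_ignored():
    document = {
        "graphs": [
            {
                "nodes": [{"id": "A:1", "lbl": "a"}, {"id": "A:2", "lbl": "b"}],
                "edges": [{"sub": "A:2", "pred": "part_of", "obj": "A:1"}],
            }
        ]
    }
    graph = load_ontology(document)
    assert not graph.is_ancestor("A:1", "A:2")


def test_fixture_round_trips_through_obograph_serialization(graph):
    reloaded = load_ontology(graph.to_obograph())
    assert reloaded.terms == graph.terms
    assert reloaded.parents == graph.parents
    assert reloaded.primary_of == graph.primary_of


def test_fixture_dict_is_deterministic():
    assert fixture_ontology_dict() == fixture_ontology_dict()
    assert make_fixture_ontology().terms == make_fixture_ontology().terms


@pytest.mark.parametrize("trial_seed", range(20))
def test_is_ancestor_matches_closure_oracle_on_random_dags(trial_seed):
    rng = random.Random(trial_seed)
    n_nodes = 50
    edges = random_dag(rng, n_nodes)
    graph = graph_from_edges(n_nodes, edges)
    closure = closure_oracle(n_nodes, edges)
    for child in range(n_nodes):
        for parent in range(n_nodes):
            assert graph.is_ancestor(f"T:{parent:04d}", f"T:{child:04d}") == bool(
                closure[child, parent]
            )
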