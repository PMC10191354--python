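"""Minimal ontology-graph service backing the HPO validators.

Loads an OBO-graph JSON document (the dialect the real HPO ships in),
honouring only ``is_a`` edges, and answers strict-ancestor and
obsolete-to-primary queries.  A deterministic ~25-term miniature
HPO-like fixture is generated programmatically so all ontology-aware
validators are testable offline; the real HPO obograph file can be
dropped in without code changes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

__all__ = [
    "OntologyLoadError",
    "UnknownTermError",
    "OntologyGraph",
    "load_ontology",
    "make_fixture_ontology",
    "fixture_ontology_dict",
]

_REPLACED_BY_PREDS = {"IAO:0100001", "replaced_by", "term_replaced_by"}


class OntologyLoadError(ValueError):
    pass


class UnknownTermError(KeyError):
    pass


def _to_curie(identifier: str) -> str:
    """Normalize an IRI-form id to a CURIE by its last path segment."""
    if "://" in identifier:
        identifier = identifier.rsplit("/", 1)[-1].rsplit("#", 1)[-1]
        identifier = identifier.replace("_", ":", 1)
    return identifier


@dataclass
class OntologyGraph:
    """DAG of terms with is-a parent edges and obsolete→primary mappings."""

    terms: set[str] = field(default_factory=set)
    labels: dict[str, str] = field(default_factory=dict)
    parents: dict[str, set[str]] = field(default_factory=dict)
    primary_of: dict[str, str] = field(default_factory=dict)
    roots: set[str] = field(default_factory=set)

    def __contains__(self, identifier: str) -> bool:
        return identifier in self.terms or identifier in self.primary_of

    def primary_id(self, identifier: str) -> str:
        """Current primary id for a term or mapped alternate; identity for
        non-obsolete terms."""
        if identifier in self.terms:
            return identifier
        if identifier in self.primary_of:
            return self.primary_of[identifier]
        raise UnknownTermError(f"unknown ontology term {identifier!r}")

    def label(self, identifier: str) -> str:
        return self.labels.get(self.primary_id(identifier), "")

    def ancestors(self, identifier: str) -> set[str]:
        """All strict ancestors (the term itself is excluded)."""
        start = self.primary_id(identifier)
        seen: set[str] = set()
        stack = list(self.parents.get(start, ()))
        while stack:
            node = stack.pop()
            if node in seen:
                continue
            seen.add(node)
            stack.extend(self.parents.get(node, ()))
        return seen

    def is_ancestor(self, candidate: str, descendant: str) -> bool:
        """True iff ``candidate`` is a *strict* ancestor of ``descendant``."""
        return self.primary_id(candidate) in self.ancestors(descendant)

    def to_obograph(self) -> dict:
        nodes = []
        for term in sorted(self.terms):
            node: dict = {"id": term, "lbl": self.labels.get(term, "")}
            nodes.append(node)
        for alt, primary in sorted(self.primary_of.items()):
            nodes.append(
                {
                    "id": alt,
                    "lbl": f"obsolete {self.labels.get(primary, '')}",
                    "meta": {
                        "deprecated": True,
                        "basicPropertyValues": [
                            {"pred": "IAO:0100001", "val": primary}
                        ],
                    },
                }
            )
        edges = [
            {"sub": child, "pred": "is_a", "obj": parent}
            for child in sorted(self.parents)
            for parent in sorted(self.parents[child])
        ]
        return {"graphs": [{"nodes": nodes, "edges": edges}]}


def _check_acyclic(graph: OntologyGraph) -> None:
    # Kahn's algorithm over child -> parent edges.
    out_degree = {t: len(graph.parents.get(t, ())) for t in graph.terms}
    children: dict[str, set[str]] = {t: set() for t in graph.terms}
    for child, parents in graph.parents.items():
        for parent in parents:
            children[parent].add(child)
    queue = [t for t, d in out_degree.items() if d == 0]
    visited = 0
    while queue:
        node = queue.pop()
        visited += 1
        for child in children[node]:
            out_degree[child] -= 1
            if out_degree[child] == 0:
                queue.append(child)
    if visited != len(graph.terms):
        raise OntologyLoadError("the is-a graph contains a cycle")


def load_ontology(source) -> OntologyGraph:
    """Load an OBO-graph JSON ontology from a path, file object, JSON text,
    or an already-parsed dict.  Only ``is_a`` edges are honoured."""
    if isinstance(source, dict):
        document = source
    elif isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
        document = json.loads(source)
    elif hasattr(source, "read"):
        document = json.load(source)
    else:
        with open(source, encoding="utf-8") as fh:
            document = json.load(fh)

    graphs = document.get("graphs")
    if not graphs:
        raise OntologyLoadError("no 'graphs' entry in OBO-graph document")
    data = graphs[0]

    graph = OntologyGraph()
    replaced: dict[str, str] = {}
    for node in data.get("nodes", []):
        node_id = _to_curie(node["id"])
        meta = node.get("meta") or {}
        if meta.get("deprecated"):
            for prop in meta.get("basicPropertyValues", []):
                if _to_curie(prop.get("pred", "")) in _REPLACED_BY_PREDS:
                    replaced[node_id] = _to_curie(prop["val"])
            continue
        graph.terms.add(node_id)
        graph.labels[node_id] = node.get("lbl", "")

    for edge in data.get("edges", []):
        if edge.get("pred") != "is_a":
            continue
        child, parent = _to_curie(edge["sub"]), _to_curie(edge["obj"])
        if child in graph.terms and parent in graph.terms:
            graph.parents.setdefault(child, set()).add(parent)

    for alt, primary in replaced.items():
        # Collapse chains so primary_of is idempotent.
        while primary in replaced:
            primary = replaced[primary]
        if primary not in graph.terms:
            raise OntologyLoadError(
                f"obsolete term {alt} replaced by {primary}, "
                f"which is not in the graph"
            )
        graph.primary_of[alt] = primary

    graph.roots = {t for t in graph.terms if not graph.parents.get(t)}
    _check_acyclic(graph)
    return graph


# Miniature HPO-like fixture.  Every term keeps its public HPO id and label;
# no ids are invented.
_FIXTURE_TERMS: list[tuple[str, str, list[str]]] = [
    ("HP:0000001", "All", []),
    ("HP:0000118", "Phenotypic abnormality", ["HP:0000001"]),
    ("HP:0012823", "Clinical modifier", ["HP:0000001"]),
    ("HP:0003674", "Onset", ["HP:0012823"]),
    ("HP:0011463", "Childhood onset", ["HP:0003674"]),
    ("HP:0003581", "Adult onset", ["HP:0003674"]),
    ("HP:0003577", "Congenital onset", ["HP:0003674"]),
    ("HP:0012824", "Severity", ["HP:0012823"]),
    ("HP:0012825", "Mild", ["HP:0012824"]),
    ("HP:0012828", "Severe", ["HP:0012824"]),
    ("HP:0000478", "Abnormality of the eye", ["HP:0000118"]),
    ("HP:0001083", "Ectopia lentis", ["HP:0000478"]),
    ("HP:0000545", "Myopia", ["HP:0000478"]),
    ("HP:0001626", "Abnormality of the cardiovascular system", ["HP:0000118"]),
    ("HP:0001679", "Abnormal aortic morphology", ["HP:0001626"]),
    ("HP:0004942", "Aortic aneurysm", ["HP:0001679"]),
    ("HP:0002616", "Aortic root aneurysm", ["HP:0004942"]),
    ("HP:0001634", "Mitral valve prolapse", ["HP:0001626"]),
    ("HP:0000924", "Abnormality of the skeletal system", ["HP:0000118"]),
    ("HP:0001167", "Abnormality of finger", ["HP:0000924"]),
    ("HP:0001166", "Arachnodactyly", ["HP:0001167"]),
    ("HP:0001382", "Joint hypermobility", ["HP:0000924"]),
    ("HP:0001507", "Growth abnormality", ["HP:0000118"]),
    ("HP:0000098", "Tall stature", ["HP:0001507"]),
    ("HP:0002086", "Abnormality of the respiratory system", ["HP:0000118"]),
    ("HP:0002107", "Pneumothorax", ["HP:0002086"]),
]

# obsolete alternate id -> current primary id
_FIXTURE_OBSOLETE = {"HP:0002631": "HP:0002616"}


def fixture_ontology_dict() -> dict:
    """The fixture ontology as an OBO-graph JSON tree (deterministic)."""
    nodes = [
        {"id": term, "lbl": label} for term, label, _ in _FIXTURE_TERMS
    ]
    for alt, primary in _FIXTURE_OBSOLETE.items():
        nodes.append(
            {
                "id": alt,
                "lbl": "obsolete Aortic root aneurysm",
                "meta": {
                    "deprecated": True,
                    "basicPropertyValues": [{"pred": "IAO:0100001", "val": primary}],
                },
            }
        )
    edges = [
        {"sub": term, "pred": "is_a", "obj": parent}
        for term, _, parents in _FIXTURE_TERMS
        for parent in parents
    ]
    return {"graphs": [{"id": "hp-fixture", "nodes": nodes, "edges": edges}]}


def make_fixture_ontology() -> OntologyGraph:
    """Deterministic miniature HPO-like DAG used by tests and examples."""
    return load_ontology(fixture_ontology_dict())
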