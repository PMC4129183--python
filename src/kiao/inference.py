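"""Entailment over the model's axioms, and model validation.

Two inferences matter in practice.  First, because each element-link
property is a subproperty of ``obo:has_part`` and ``has_part`` is
transitive along the annotation -> statement -> element chain, a graph
annotation has every reified element of its statements as a part; these
derived ``has_part`` quads are what make "all parts of this annotation"
queries one-step.  Second, the element-link properties have a declared
domain (``RdfStatement``) and range (``RdfStatementElement``), so the
type quads the builders materialize are recoverable by plain RDFS
domain/range reasoning.

Inferred quads are returned in a distinguished ``inferred`` graph and
are never stored in content graphs, so the cost accounting can exclude
them (the parenthesized figures of the count report include the
materialized, inferable type quads; inferred has_part quads are never
counted).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

from .store import AnnotationStore, GraphAnnotation, Quad, Term

#: named graph that holds inferred quads when they are serialized
INFERRED_GRAPH_LOCAL = "inferredQuads"


def inferred_graph_iri(store: AnnotationStore) -> str:
    return store.vocab.namespaces["kiao"] + INFERRED_GRAPH_LOCAL


def infer_has_part(store: AnnotationStore) -> set[Quad]:
    """All derivable (annotation, obo:has_part, element) quads.

    Transitivity is applied only along the reification chain; arbitrary
    partonomies in content graphs are not touched.
    """
    v, g = store.vocab, inferred_graph_iri(store)
    has_part = Term.iri(v["has_part"])
    out: set[Quad] = set()
    for stmt in store.statements.values():
        for el_id in stmt.elements.values():
            out.add(Quad(Term.iri(stmt.parent_annotation), has_part,
                         Term.iri(el_id), graph=g))
    return out


def infer_types(store: AnnotationStore) -> set[Quad]:
    """rdf:type quads entailed by the element-link domains and ranges."""
    v, g = store.vocab, inferred_graph_iri(store)
    rdf_type = Term.iri(v["type"])
    links = set(store.vocab.element_link_properties())
    out: set[Quad] = set()
    for quad in store.quads:
        if quad.graph is None and quad.predicate.value in links:
            out.add(Quad(quad.subject, rdf_type, Term.iri(v["RdfStatement"]), graph=g))
            if not quad.obj.is_literal:
                out.add(Quad(Term.iri(quad.obj.value), rdf_type,
                             Term.iri(v["RdfStatementElement"]), graph=g))
    return out


@dataclass(frozen=True)
class Violation:
    """One validation finding; ``severity`` is 'error' or 'warning'."""

    code: str
    severity: str
    subject: str
    message: str

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


def validate(store: AnnotationStore) -> list[Violation]:
    """Check the store against the model's invariants.

    Violations are data, not exceptions: a store loaded from disk may
    legitimately contain them and still be explorable.  Codes:

    - ``multi-denotation`` — an annotation or element with != 1
      outgoing ``iao:denotes`` quad;
    - ``empty-graph-annotation`` — a content graph with no quads;
    - ``orphan-element`` — an element whose parent statement link is
      missing or duplicated;
    - ``element-source-mismatch`` — an element denoting something other
      than its position in the parent's source quad;
    - ``unresolved-statement`` — a reified statement whose source
      triple could not be matched to a content quad;
    - ``dangling-based-on`` — a ``basedOn`` quad with an endpoint that
      is no known ICE;
    - ``based-on-cycle`` (warning) — the provenance relation is
      declared transitive, not acyclic, but cycles usually indicate an
      error;
    - ``literal-element`` (warning) — an object element denoting a
      literal, permitted but flagged.
    """
    v = store.vocab
    violations: list[Violation] = []
    denotes = Term.iri(v["denotes"])

    def denote_count(ice_id: str) -> int:
        return sum(1 for _ in store.match(Term.iri(ice_id), denotes))

    for ann in store.annotations.values():
        n = denote_count(ann.id)
        if n != 1:
            violations.append(Violation(
                "multi-denotation", "error", ann.id,
                f"annotation has {n} iao:denotes quads (exactly 1 required)"))
        if isinstance(ann, GraphAnnotation):
            content = [q for q in store.quads if q.graph == ann.graph_name]
            if not content:
                violations.append(Violation(
                    "empty-graph-annotation", "error", ann.id,
                    f"content graph {ann.graph_name} holds no statements "
                    "(one or more required)"))

    link_props = {p: pos for pos, p in
                  zip(("subject", "property", "object"),
                      v.element_link_properties())}
    for el in store.elements.values():
        incoming = [q for q in store.match(None, None, Term.iri(el.id))
                    if q.predicate.value in link_props]
        if len(incoming) != 1:
            violations.append(Violation(
                "orphan-element", "error", el.id,
                f"element has {len(incoming)} incoming position links "
                "(exactly 1 required)"))
        n = denote_count(el.id)
        if n != 1:
            violations.append(Violation(
                "multi-denotation", "error", el.id,
                f"statement element has {n} iao:denotes quads"))
        stmt = store.statements.get(el.parent_statement)
        if stmt is None or stmt.source_quad is None:
            continue
        expected = {"subject": stmt.source_quad.subject,
                    "property": stmt.source_quad.predicate,
                    "object": stmt.source_quad.obj}[el.position]
        actual = [q.obj for q in store.match(Term.iri(el.id), denotes)]
        if actual and actual[0] != expected:
            violations.append(Violation(
                "element-source-mismatch", "error", el.id,
                f"element denotes {actual[0].value!r} but the {el.position} "
                f"position of its statement is {expected.value!r}"))
        if el.denoted.is_literal:
            violations.append(Violation(
                "literal-element", "warning", el.id,
                "object element denotes a literal"))

    for stmt in store.statements.values():
        if stmt.source_quad is None:
            violations.append(Violation(
                "unresolved-statement", "warning", stmt.id,
                "reified statement could not be matched to a content quad"))
        elif stmt.source_quad not in store.quads:
            violations.append(Violation(
                "unresolved-statement", "error", stmt.id,
                "the content quad this statement reifies is absent"))

    known = store.known_ices()
    edges = store.based_on_edges()
    for subject, obj in sorted(edges):
        for endpoint in (subject, obj):
            if endpoint not in known:
                violations.append(Violation(
                    "dangling-based-on", "error", endpoint,
                    f"basedOn edge ({subject}, {obj}) references an unknown ICE"))

    for node in sorted(_nodes_on_cycles(edges)):
        violations.append(Violation(
            "based-on-cycle", "warning", node,
            "ICE participates in a basedOn cycle"))

    return violations


def _nodes_on_cycles(edges: set[tuple[str, str]]) -> set[str]:
    import networkx as nx
    graph = nx.DiGraph(sorted(edges))
    out: set[str] = set()
    for component in nx.strongly_connected_components(graph):
        if len(component) > 1 or any((n, n) in edges for n in component):
            out |= component
    return out


def violations_as_jsonl(violations: list[Violation]) -> str:
    return "\n".join(v.to_json() for v in violations)
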