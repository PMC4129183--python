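"""Quad container and builders for annotations and their provenance.

The :class:`AnnotationStore` partitions its quads into the default
graph — which holds annotation, reification and provenance assertions —
and one named graph per graph annotation holding that annotation's
content statements.  Keeping the content in its own graph separates
*what an annotation says* from *asserting it is true*: a reader of the
store is never committed to the propositions inside a content graph.

``rdf:type`` quads emitted by the builders are materialized but tagged
as *inferable*, because they follow from the declared domains and
ranges; the cost accounting reports counts both with and without them.

Blank nodes are disallowed throughout: element-level provenance needs
every statement position to denote a referable term, so callers must
skolemize first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from .vocabulary import DEFAULT_VOCAB, Vocab

POSITIONS = ("subject", "property", "object")

#: distinguished marker for the default graph
DEFAULT_GRAPH: Optional[str] = None


class StoreError(ValueError):
    """Raised on violations of the store's preconditions."""


class ProvenanceCycleWarning(UserWarning):
    """A basedOn edge closed a cycle (permitted unless strict_cycles)."""


@dataclass(frozen=True)
class Term:
    """An RDF node: IRI or literal (with optional datatype or language)."""

    value: str
    is_literal: bool = False
    datatype: Optional[str] = None
    language: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.is_literal and (self.datatype or self.language):
            raise StoreError("IRIs carry no datatype or language")
        if self.datatype and self.language:
            raise StoreError("a literal has a datatype or a language tag, not both")
        if not self.is_literal and self.value.startswith("_:"):
            raise StoreError("blank nodes are disallowed; skolemize first")

    @classmethod
    def iri(cls, value: str) -> "Term":
        return cls(value)

    @classmethod
    def literal(cls, value: str, datatype: str | None = None,
                language: str | None = None) -> "Term":
        return cls(value, is_literal=True, datatype=datatype, language=language)


def _as_term(node: "Term | str", *, allow_literal: bool = False) -> Term:
    term = Term.iri(node) if isinstance(node, str) else node
    if term.is_literal and not allow_literal:
        raise StoreError(f"expected an IRI, got literal {term.value!r}")
    return term


def term_key(term: Term) -> tuple:
    """Stable sort key (Optional fields made comparable)."""
    return (term.is_literal, term.value, term.datatype or "", term.language or "")


def quad_key(quad: "Quad") -> tuple:
    return (quad.graph or "", term_key(quad.subject), term_key(quad.predicate),
            term_key(quad.obj))


@dataclass(frozen=True)
class Quad:
    """One statement in a graph: the graph is an IRI or the default graph."""

    subject: Term
    predicate: Term
    obj: Term
    graph: Optional[str] = DEFAULT_GRAPH

    def __post_init__(self) -> None:
        if self.subject.is_literal:
            raise StoreError("literals may not appear in subject position")
        if self.predicate.is_literal:
            raise StoreError("predicates are always IRIs")

    def triple(self) -> tuple[Term, Term, Term]:
        return (self.subject, self.predicate, self.obj)


@dataclass
class ResourceAnnotation:
    """Annotation denoting a single RDF resource (``ra`` instances)."""

    id: str
    denoted: Term
    note: Optional[str] = None  # opaque target note; never model quads


@dataclass
class GraphAnnotation:
    """Annotation denoting the content of a named graph (``ga`` instances)."""

    id: str
    graph_name: str
    content: list[Quad] = field(default_factory=list)
    note: Optional[str] = None


@dataclass
class ReifiedStatement:
    """ICE surrogate for one content quad of a graph annotation."""

    id: str
    parent_annotation: str
    source_quad: Optional[Quad]
    elements: dict[str, str] = field(default_factory=dict)  # position -> element id


@dataclass
class StatementElement:
    """ICE surrogate for one position of a reified statement."""

    id: str
    parent_statement: str
    position: str
    denoted: Term


class AnnotationStore:
    """Annotations, reified statements, elements and basedOn edges.

    Parameters
    ----------
    vocab:
        Namespace policy; defaults to the documented model namespaces.
    strict_cycles:
        When true, a basedOn edge that would close a cycle raises
        instead of warning.  The relation is declared transitive, not
        acyclic, so cycles are representable; they are still usually a
        modeling error, hence the warning.
    """

    def __init__(self, vocab: Vocab | None = None, *, strict_cycles: bool = False):
        self.vocab = vocab or DEFAULT_VOCAB
        self.strict_cycles = strict_cycles
        self._quads: set[Quad] = set()
        self._inferable_types: set[Quad] = set()
        self.annotations: dict[str, ResourceAnnotation | GraphAnnotation] = {}
        self.statements: dict[str, ReifiedStatement] = {}
        self.elements: dict[str, StatementElement] = {}
        self.extra_quads: set[Quad] = set()  # non-model quads, preserved opaquely
        self._counters: dict[str, int] = {}

    # -- raw quad access --------------------------------------------------

    @property
    def quads(self) -> frozenset[Quad]:
        return frozenset(self._quads | self.extra_quads)

    def __len__(self) -> int:
        return len(self._quads) + len(self.extra_quads)

    def __contains__(self, quad: Quad) -> bool:
        return quad in self._quads or quad in self.extra_quads

    def is_inferable_type(self, quad: Quad) -> bool:
        return quad in self._inferable_types

    def _add(self, quad: Quad, *, inferable_type: bool = False) -> None:
        self._quads.add(quad)
        if inferable_type:
            self._inferable_types.add(quad)

    def add_extra_quad(self, quad: Quad) -> None:
        """Preserve a quad that is not part of the annotation model."""
        self.extra_quads.add(quad)

    def match(self, subject: Term | None = None, predicate: Term | None = None,
              obj: Term | None = None, graph: Optional[str] = DEFAULT_GRAPH,
              *, any_graph: bool = False) -> Iterator[Quad]:
        for quad in self._quads | self.extra_quads:
            if subject is not None and quad.subject != subject:
                continue
            if predicate is not None and quad.predicate != predicate:
                continue
            if obj is not None and quad.obj != obj:
                continue
            if not any_graph and quad.graph != graph:
                continue
            yield quad

    # -- identity helpers --------------------------------------------------

    def known_ices(self) -> set[str]:
        """IRIs of every information content entity the store knows."""
        return set(self.annotations) | set(self.statements) | set(self.elements)

    def _used_iris(self) -> set[str]:
        used = self.known_ices()
        used.update(a.graph_name for a in self.annotations.values()
                    if isinstance(a, GraphAnnotation))
        return used

    def mint(self, kind: str, label_hint: str = "") -> str:
        """Next free mnemonic IRI of the given kind (ra/ga/s/se/g)."""
        used = self._used_iris()
        counter = self._counters.get(kind, 0) + 1
        while True:
            try:
                iri = self.vocab.mint_iri(kind, label_hint, counter, existing=used)
                break
            except Exception:
                counter += 1
        self._counters[kind] = counter
        return iri

    # -- builders ----------------------------------------------------------

    def create_resource_annotation(self, denoted: Term | str,
                                   id: str | None = None,
                                   note: str | None = None) -> ResourceAnnotation:
        """Add an annotation denoting a single resource.

        Emits ``(id, rdf:type, kiao:RdfResourceAnnotation)`` (tagged
        inferable) and ``(id, iao:denotes, denoted)`` in the default
        graph.  Several annotations may denote the same resource.
        """
        denoted_term = _as_term(denoted)
        ann_id = self._claim_id(id, "resource-annotation")
        v = self.vocab
        self._add(Quad(Term.iri(ann_id), Term.iri(v["type"]),
                       Term.iri(v["RdfResourceAnnotation"])), inferable_type=True)
        self._add(Quad(Term.iri(ann_id), Term.iri(v["denotes"]), denoted_term))
        ann = ResourceAnnotation(ann_id, denoted_term, note)
        self.annotations[ann_id] = ann
        return ann

    def create_graph_annotation(self, content: Iterable[tuple], id: str | None = None,
                                graph_name: str | None = None,
                                note: str | None = None) -> GraphAnnotation:
        """Add an annotation denoting the content of a named graph.

        ``content`` is a non-empty iterable of (s, p, o) triples (Terms
        or IRI strings; objects may be literal Terms).  Each triple is
        stored as a quad in the annotation's content graph; the
        annotation's type and denotes quads go to the default graph.
        """
        triples = [(
            _as_term(s), _as_term(p), _as_term(o, allow_literal=True),
        ) for s, p, o in content]
        if not triples:
            raise StoreError("a graph annotation denotes one or more RDF statements")
        ann_id = self._claim_id(id, "graph-annotation")
        if graph_name is None:
            graph_name = self.mint("graph")
        elif any(isinstance(a, GraphAnnotation) and a.graph_name == graph_name
                 for a in self.annotations.values()):
            # one graph per annotation: denotation of a shared graph is forbidden
            raise StoreError(f"graph {graph_name} is already denoted by another annotation")
        v = self.vocab
        self._add(Quad(Term.iri(ann_id), Term.iri(v["type"]),
                       Term.iri(v["RdfGraphAnnotation"])), inferable_type=True)
        self._add(Quad(Term.iri(ann_id), Term.iri(v["denotes"]), Term.iri(graph_name)))
        quads = []
        for s, p, o in triples:
            quad = Quad(s, p, o, graph=graph_name)
            self._add(quad)
            quads.append(quad)
        ann = GraphAnnotation(ann_id, graph_name, quads, note)
        self.annotations[ann_id] = ann
        return ann

    def _claim_id(self, id: str | None, kind: str) -> str:
        if id is None:
            return self.mint(kind)
        if id in self._used_iris():
            raise StoreError(f"IRI {id} is already in use")
        return id

    # -- provenance --------------------------------------------------------

    def assert_based_on(self, subject_ice: str, object_ice: str) -> Quad:
        """Record that one ICE was created relying on another.

        Both endpoints must be ICEs known to the store (annotations,
        reified statements, or statement elements); the relation has no
        cardinality restriction, so arbitrary fan-in and fan-out are
        fine.  Duplicate assertions are idempotent.  Edges closing a
        cycle warn by default (`strict_cycles` rejects them).
        """
        if subject_ice == object_ice:
            raise StoreError(f"{subject_ice} cannot be based on itself")
        known = self.known_ices()
        for endpoint in (subject_ice, object_ice):
            if endpoint not in known:
                raise StoreError(f"{endpoint} is not an ICE known to this store")
        quad = Quad(Term.iri(subject_ice), Term.iri(self.vocab["basedOn"]),
                    Term.iri(object_ice))
        if quad not in self._quads and self._would_cycle(subject_ice, object_ice):
            if self.strict_cycles:
                raise StoreError(
                    f"basedOn edge {subject_ice} -> {object_ice} closes a cycle")
            warnings.warn(
                f"basedOn edge {subject_ice} -> {object_ice} closes a cycle",
                ProvenanceCycleWarning, stacklevel=2)
        self._add(quad)
        return quad

    def _would_cycle(self, subject_ice: str, object_ice: str) -> bool:
        # cycle iff subject is already reachable downstream from object
        stack, seen = [object_ice], set()
        edges = self.based_on_edges()
        while stack:
            node = stack.pop()
            if node == subject_ice:
                return True
            if node in seen:
                continue
            seen.add(node)
            stack.extend(o for s, o in edges if s == node)
        return False

    def based_on_edges(self) -> set[tuple[str, str]]:
        """Direct (subject, object) basedOn pairs in the default graph."""
        based_on = Term.iri(self.vocab["basedOn"])
        return {(q.subject.value, q.obj.value)
                for q in self._quads
                if q.graph is DEFAULT_GRAPH and q.predicate == based_on}

    # -- lookups -----------------------------------------------------------

    def annotation(self, ann_id: str) -> ResourceAnnotation | GraphAnnotation:
        try:
            return self.annotations[ann_id]
        except KeyError:
            raise StoreError(f"unknown annotation {ann_id}") from None

    def statements_of(self, ann_id: str) -> list[ReifiedStatement]:
        return sorted((s for s in self.statements.values()
                       if s.parent_annotation == ann_id), key=lambda s: s.id)

    def elements_of(self, stmt_id: str) -> list[StatementElement]:
        stmt = self.statements[stmt_id]
        return [self.elements[eid] for _, eid in sorted(stmt.elements.items())]

    def remove_quad(self, quad: Quad) -> None:
        """Drop a quad without touching the indexes (corruption harness)."""
        self._quads.discard(quad)
        self._inferable_types.discard(quad)
        self.extra_quads.discard(quad)

    def copy(self) -> "AnnotationStore":
        import copy as _copy
        clone = AnnotationStore(self.vocab, strict_cycles=self.strict_cycles)
        clone._quads = set(self._quads)
        clone._inferable_types = set(self._inferable_types)
        clone.extra_quads = set(self.extra_quads)
        clone.annotations = _copy.deepcopy(self.annotations)
        clone.statements = _copy.deepcopy(self.statements)
        clone.elements = _copy.deepcopy(self.elements)
        clone._counters = dict(self._counters)
        return clone


__all__ = [
    "AnnotationStore", "DEFAULT_GRAPH", "GraphAnnotation", "POSITIONS",
    "ProvenanceCycleWarning", "Quad", "ReifiedStatement", "ResourceAnnotation",
    "StatementElement", "StoreError", "Term",
]
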