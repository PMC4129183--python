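"""Statement and statement-element reification.

Annotation-level ``basedOn`` edges say *that* one annotation relied on
another; they cannot say *which element* of which content statement did
the relying.  To record that, a content quad is reified as an
information content entity (an ``RdfStatement``, linked from its graph
annotation by ``obo:has_part``), and each of its subject / property /
object positions may be reified as an ``RdfStatementElement`` linked by
the corresponding element property (each a subproperty of
``obo:has_part``).  Every element denotes the term at its position, so
the source triple is exactly recoverable from a fully reified
statement, and ``basedOn`` edges from elements to annotations or to
other elements carry the fine-grained provenance.

Partial reification is deliberate: only the positions whose provenance
matters need elements (in practice the property position rarely does).
A statement shared verbatim by two content graphs is reified separately
under each graph annotation.
"""

from __future__ import annotations

from .store import (AnnotationStore, GraphAnnotation, Quad, ReifiedStatement,
                    StatementElement, StoreError, Term, POSITIONS)


def reify_statement(store: AnnotationStore, ga: GraphAnnotation | str,
                    triple: tuple, id: str | None = None) -> ReifiedStatement:
    """Reify one content triple of a graph annotation.

    Emits ``(ga, obo:has_part, s)`` plus the inferable type quad
    ``(s, rdf:type, kiao:RdfStatement)``; the returned handle has no
    elements yet.  Idempotent: reifying the same triple of the same
    annotation twice returns the existing handle.
    """
    if isinstance(ga, str):
        ga = store.annotation(ga)  # type: ignore[assignment]
    if not isinstance(ga, GraphAnnotation):
        raise StoreError(f"{ga!r} is not a graph annotation")
    s, p, o = (_coerce(t) for t in triple)
    quad = Quad(s, p, o, graph=ga.graph_name)
    if quad not in ga.content:
        raise StoreError(
            f"triple is not in the content graph {ga.graph_name} of {ga.id}")
    for existing in store.statements.values():
        if existing.parent_annotation == ga.id and existing.source_quad == quad:
            return existing
    stmt_id = id if id is not None else store.mint("statement")
    if id is not None and id in store.known_ices():
        raise StoreError(f"IRI {id} is already in use")
    v = store.vocab
    store._add(Quad(Term.iri(ga.id), Term.iri(v["has_part"]), Term.iri(stmt_id)))
    store._add(Quad(Term.iri(stmt_id), Term.iri(v["type"]),
                    Term.iri(v["RdfStatement"])), inferable_type=True)
    stmt = ReifiedStatement(stmt_id, ga.id, quad)
    store.statements[stmt_id] = stmt
    return stmt


def reify_element(store: AnnotationStore, stmt: ReifiedStatement | str,
                  position: str, id: str | None = None) -> StatementElement:
    """Reify one position of a reified statement.

    Emits the position link quad (``kiao:subjectElement`` /
    ``propertyElement`` / ``objectElement``), the element's
    ``iao:denotes`` quad — its object copied from the source quad at
    that position — and an inferable type quad.  Idempotent per
    position.  An object-position element may denote a literal; the
    validator flags such elements for review.
    """
    if isinstance(stmt, str):
        try:
            stmt = store.statements[stmt]
        except KeyError:
            raise StoreError(f"unknown reified statement {stmt}") from None
    if position not in POSITIONS:
        raise StoreError(f"unknown statement position {position!r}")
    if position in stmt.elements:
        return store.elements[stmt.elements[position]]
    if stmt.source_quad is None:
        raise StoreError(f"statement {stmt.id} has no resolved source quad")
    denoted = {"subject": stmt.source_quad.subject,
               "property": stmt.source_quad.predicate,
               "object": stmt.source_quad.obj}[position]
    el_id = id if id is not None else store.mint("statement-element")
    if id is not None and id in store.known_ices():
        raise StoreError(f"IRI {id} is already in use")
    v = store.vocab
    store._add(Quad(Term.iri(stmt.id), Term.iri(v.position_property(position)),
                    Term.iri(el_id)))
    store._add(Quad(Term.iri(el_id), Term.iri(v["denotes"]), denoted))
    store._add(Quad(Term.iri(el_id), Term.iri(v["type"]),
                    Term.iri(v["RdfStatementElement"])), inferable_type=True)
    element = StatementElement(el_id, stmt.id, position, denoted)
    store.elements[el_id] = element
    stmt.elements[position] = el_id
    return element


def reify_fully(store: AnnotationStore, ga: GraphAnnotation | str,
                triple: tuple) -> ReifiedStatement:
    """Reify a triple and all three of its positions."""
    stmt = reify_statement(store, ga, triple)
    for position in POSITIONS:
        reify_element(store, stmt, position)
    return stmt


def assert_element_provenance(store: AnnotationStore,
                              element: StatementElement | str,
                              basis: str) -> Quad:
    """Record that a statement element is based on another ICE.

    The basis may be an annotation or another statement element (the
    same ``basedOn`` relation serves both granularities); the edge is
    delegated to the store's annotation-level machinery.
    """
    el_id = element.id if isinstance(element, StatementElement) else element
    if el_id not in store.elements:
        raise StoreError(f"{el_id} is not a statement element of this store")
    return store.assert_based_on(el_id, basis)


def reconstruct_triple(store: AnnotationStore,
                       stmt: ReifiedStatement | str) -> tuple[Term, Term, Term]:
    """Source triple of a fully reified statement, from its elements only."""
    if isinstance(stmt, str):
        stmt = store.statements[stmt]
    missing = [p for p in POSITIONS if p not in stmt.elements]
    if missing:
        raise StoreError(f"statement {stmt.id} lacks elements for {missing}")
    s, p, o = (store.elements[stmt.elements[pos]].denoted for pos in POSITIONS)
    return (s, p, o)


def _coerce(node) -> Term:
    return Term.iri(node) if isinstance(node, str) else node
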