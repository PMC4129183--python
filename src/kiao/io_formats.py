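"""Reading and writing stores as TriG and N-Quads.

TriG is the primary on-disk format because the model needs named
graphs; N-Quads is supported for interchange, and Turtle is used for
the TBox only.  Writing is canonical — graphs sorted by IRI with the
default graph first, quads in lexicographic term order, prefixes fixed
by the vocabulary — so a written document is byte-stable: write, read,
write yields the identical document.  Parsing goes through rdflib;
term text (IRI brackets, literal escaping, datatype/language tags)
also goes through rdflib's N3 machinery rather than hand-rolled
escaping.

Reading reconstructs the model indexes by pattern-matching model
quads.  Quads that match no model pattern are preserved opaquely and
written back unchanged, so a round trip never loses information even
for documents that only partially follow the model.
"""

from __future__ import annotations

from typing import Iterable

from rdflib import Dataset, Graph, Literal, URIRef

from .store import (AnnotationStore, DEFAULT_GRAPH, GraphAnnotation, Quad,
                    ReifiedStatement, ResourceAnnotation, StatementElement,
                    StoreError, Term, term_key)
from .vocabulary import Vocab

FORMATS = ("trig", "nquads")


class FormatError(StoreError):
    """Unsupported format or unparseable document."""


# -- term conversion -------------------------------------------------------

def term_to_rdflib(term: Term):
    if term.is_literal:
        return Literal(term.value, datatype=term.datatype or None,
                       lang=term.language or None)
    return URIRef(term.value)


def term_from_rdflib(node) -> Term:
    if isinstance(node, Literal):
        return Term.literal(str(node),
                            datatype=str(node.datatype) if node.datatype else None,
                            language=node.language)
    if isinstance(node, URIRef):
        return Term.iri(str(node))
    raise FormatError(f"blank node {node!r} encountered; the model requires "
                      "skolemized documents")


def to_rdflib_graph(store: AnnotationStore) -> Graph:
    """Default-graph quads as an rdflib Graph (for SPARQL)."""
    graph = Graph()
    _bind(graph, store.vocab)
    for quad in store.quads:
        if quad.graph is DEFAULT_GRAPH:
            graph.add((term_to_rdflib(quad.subject), term_to_rdflib(quad.predicate),
                       term_to_rdflib(quad.obj)))
    return graph


def to_rdflib_dataset(store: AnnotationStore) -> Dataset:
    dataset = Dataset()
    _bind(dataset, store.vocab)
    for quad in store.quads:
        target = (dataset.default_graph if quad.graph is DEFAULT_GRAPH
                  else dataset.graph(URIRef(quad.graph)))
        target.add((term_to_rdflib(quad.subject), term_to_rdflib(quad.predicate),
                    term_to_rdflib(quad.obj)))
    return dataset


def _bind(graph, vocab: Vocab) -> None:
    for prefix, base in vocab.namespaces.items():
        graph.bind(prefix, base, replace=True)


# -- writing ---------------------------------------------------------------

def write_store(store: AnnotationStore, format: str = "trig", *,
                include_inferred: bool = False) -> str:
    """Serialize the store canonically; returns the document text.

    ``include_inferred`` additionally writes the entailed has_part and
    type quads into the distinguished inferred graph.
    """
    if format not in FORMATS:
        raise FormatError(f"unsupported format {format!r} (use one of {FORMATS})")
    quads = set(store.quads)
    if include_inferred:
        from .inference import infer_has_part, infer_types
        quads |= infer_has_part(store) | infer_types(store)
    if format == "nquads":
        return _write_nquads(quads)
    return _write_trig(quads, store.vocab)


def _sort_key(quad: Quad):
    return (term_key(quad.subject), term_key(quad.predicate), term_key(quad.obj))


def _n3(term: Term, namespace_manager=None) -> str:
    return term_to_rdflib(term).n3(namespace_manager)


def _write_nquads(quads: set[Quad]) -> str:
    lines = []
    by_graph = sorted(quads, key=lambda q: (q.graph or "", _sort_key(q)))
    for quad in by_graph:
        parts = [_n3(quad.subject), _n3(quad.predicate), _n3(quad.obj)]
        if quad.graph is not DEFAULT_GRAPH:
            parts.append(f"<{quad.graph}>")
        lines.append(" ".join(parts) + " .")
    return "\n".join(lines) + ("\n" if lines else "")


def _write_trig(quads: set[Quad], vocab: Vocab) -> str:
    # bind only the model's prefixes so nothing else is ever compacted
    nm = Graph(bind_namespaces="none").namespace_manager
    for prefix, base in vocab.namespaces.items():
        nm.bind(prefix, base, replace=True)
    out = [f"@prefix {prefix}: <{base}> ."
           for prefix, base in sorted(vocab.namespaces.items())]
    out.append("")
    graphs: dict[str | None, list[Quad]] = {}
    for quad in quads:
        graphs.setdefault(quad.graph, []).append(quad)

    def emit(block: list[Quad], indent: str) -> list[str]:
        return [indent + " ".join((_n3(q.subject, nm), _n3(q.predicate, nm),
                                   _n3(q.obj, nm))) + " ."
                for q in sorted(block, key=_sort_key)]

    if DEFAULT_GRAPH in graphs:
        out.extend(emit(graphs.pop(DEFAULT_GRAPH), ""))
        out.append("")
    for name in sorted(g for g in graphs if g is not None):
        out.append(f"{URIRef(name).n3(nm)} {{")
        out.extend(emit(graphs[name], "    "))
        out.append("}")
        out.append("")
    while out and out[-1] == "":
        out.pop()
    return "\n".join(out) + "\n"


def write_tbox(vocab: Vocab) -> str:
    """The model TBox as canonical Turtle."""
    quads = {Quad(Term.iri(s), Term.iri(p), Term.iri(o))
             for s, p, o in vocab.emit_tbox()}
    return _write_trig(quads, vocab)


# -- reading ---------------------------------------------------------------

def read_store(document: str, format: str = "trig",
               vocab: Vocab | None = None) -> AnnotationStore:
    """Parse a document and reconstruct the model indexes.

    Model quads (types, denotes, has_part, element links, basedOn) are
    recognized by their vocabulary IRIs; everything else is preserved
    as opaque extra quads.  Structural problems are not fatal here —
    load the store, then run :func:`kiao.inference.validate`.
    """
    if format not in FORMATS:
        raise FormatError(f"unsupported format {format!r} (use one of {FORMATS})")
    vocab = vocab or Vocab()
    dataset = Dataset()
    try:
        dataset.parse(data=document, format="trig" if format == "trig" else "nquads")
    except Exception as exc:  # rdflib raises several parser error types
        raise FormatError(f"cannot parse document as {format}: {exc}") from exc

    quads: list[Quad] = []
    for s, p, o, ctx in dataset.quads((None, None, None, None)):
        graph_id = getattr(ctx, "identifier", ctx)
        name = (DEFAULT_GRAPH if graph_id == dataset.default_graph.identifier
                else str(graph_id))
        quads.append(Quad(term_from_rdflib(s), term_from_rdflib(p),
                          term_from_rdflib(o), graph=name))
    return _reconstruct(quads, vocab)


def _reconstruct(quads: Iterable[Quad], vocab: Vocab) -> AnnotationStore:
    store = AnnotationStore(vocab)
    quads = set(quads)
    rdf_type, denotes = Term.iri(vocab["type"]), Term.iri(vocab["denotes"])
    has_part, based_on = Term.iri(vocab["has_part"]), Term.iri(vocab["basedOn"])
    links = {iri: pos for pos, iri in zip(("subject", "property", "object"),
                                          vocab.element_link_properties())}

    def default(pred: Term) -> list[Quad]:
        return [q for q in quads if q.graph is DEFAULT_GRAPH and q.predicate == pred]

    types: dict[str, set[str]] = {}
    for q in default(rdf_type):
        if not q.obj.is_literal:
            types.setdefault(q.subject.value, set()).add(q.obj.value)
    denoted: dict[str, list[Term]] = {}
    for q in default(denotes):
        denoted.setdefault(q.subject.value, []).append(q.obj)

    consumed: set[Quad] = set()

    def take(q: Quad, *, inferable_type: bool = False) -> None:
        consumed.add(q)
        store._add(q, inferable_type=inferable_type)

    # annotations
    for subject, classes in sorted(types.items()):
        is_ra = vocab["RdfResourceAnnotation"] in classes
        is_ga = vocab["RdfGraphAnnotation"] in classes
        if not (is_ra or is_ga):
            continue
        targets = denoted.get(subject, [])
        if is_ga:
            graph_name = next((t.value for t in targets
                               if not t.is_literal
                               and any(q.graph == t.value for q in quads)), None)
            if graph_name is None and targets and not targets[0].is_literal:
                graph_name = targets[0].value  # empty content graph: validator flags it
            content = sorted((q for q in quads if q.graph == graph_name),
                             key=_sort_key) if graph_name else []
            store.annotations[subject] = GraphAnnotation(
                subject, graph_name or "", list(content))
            for q in content:
                take(q)
        else:
            target = targets[0] if targets else Term.iri(subject)
            store.annotations[subject] = ResourceAnnotation(subject, target)

    # reified statements: has_part links from graph annotations
    for q in default(has_part):
        parent = q.subject.value
        if parent in store.annotations and not q.obj.is_literal:
            stmt_id = q.obj.value
            store.statements[stmt_id] = ReifiedStatement(stmt_id, parent, None)
            take(q)

    # elements: position links from statements
    for q in sorted((q for q in quads if q.graph is DEFAULT_GRAPH
                     and q.predicate.value in links), key=_sort_key):
        stmt = store.statements.get(q.subject.value)
        if stmt is None or q.obj.is_literal:
            continue
        el_id = q.obj.value
        position = links[q.predicate.value]
        el_denoted = denoted.get(el_id, [Term.iri(el_id)])[0]
        store.elements[el_id] = StatementElement(el_id, stmt.id, position, el_denoted)
        if position not in stmt.elements:
            stmt.elements[position] = el_id
        take(q)

    _resolve_source_quads(store)

    # remaining default-graph model quads: types, denotes, basedOn
    known = store.known_ices()
    for q in quads - consumed:
        if q in consumed or q.graph is not DEFAULT_GRAPH:
            continue
        if q.predicate == rdf_type and q.subject.value in known:
            take(q, inferable_type=True)
        elif q.predicate == denotes and q.subject.value in known:
            take(q)
        elif q.predicate == based_on:
            take(q)

    for q in quads - consumed:
        store.add_extra_quad(q)
    return store


def _resolve_source_quads(store: AnnotationStore) -> None:
    """Bind each reified statement to the content quad it reifies.

    The model itself never asserts which content triple a statement
    reifies; the binding is recovered by matching element denotations
    against the parent annotation's content quads.  A statement with an
    ambiguous or empty match keeps ``source_quad=None`` and is reported
    by the validator.
    """
    for stmt in store.statements.values():
        ann = store.annotations.get(stmt.parent_annotation)
        if not isinstance(ann, GraphAnnotation):
            continue
        wanted = {pos: store.elements[el_id].denoted
                  for pos, el_id in stmt.elements.items() if el_id in store.elements}
        candidates = [
            q for q in ann.content
            if all({"subject": q.subject, "property": q.predicate,
                    "object": q.obj}[pos] == term for pos, term in wanted.items())
        ]
        if wanted and len(candidates) == 1:
            stmt.source_quad = candidates[0]
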