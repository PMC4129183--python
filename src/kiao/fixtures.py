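"""Worked-example stores and a synthetic annotation-stack generator.

Two canonical stores exercise every part of the model.

The *syntactic* store models the opening of a text-mining pipeline over
the phrase "Interferons inhibit activation of STAT6": token annotations
(ra1, ra2), part-of-speech annotations over them (ra3 -> NNS,
ra4 -> VBP), and a dependency-parse graph annotation ga1 whose single
content statement says token t2 has token t1 as its subject dependent.
ga1 is based on all four resource annotations; its statement s1 is
reified with elements se1 (object, denotes t1, based on ra1), se2
(subject, denotes t2, based on ra2) and se3 (property, no provenance —
provenance for the property position is rarely recorded).

The *semantic* store models concept annotation in the style of the
CRAFT corpus: ra5 denotes interferons (InterPro IPR000471), ra6 the
positive regulation of biological processes (GO:0048518), ra7 STAT6
proteins (PR:000001933).  ga2 denotes a dynamically constructed
subclass P1 of positive regulation in which STAT6 is the regulated
participant; ga3 denotes a subclass N1 of negative regulation
(GO:0048519) whose regulator is an interferon and whose regulated
process is P1.  The triple (P1, hasRegulatedParticipant, PR:000001933)
is reused verbatim in both content graphs; its reifications are s2 (in
ga2) and s3 (in ga3), and the element-level chain se9 -> se6 -> ra7
records that ga3's reference to STAT6 derives from ga2's.

Parts of the semantic store are *reconstructions*: the published
description fixes ga2 exactly but leaves ga3's third annotation-level
basis and the precise content of g3 open, naming only its ingredients
and the resulting triple counts (6 (7) | 3 | 32 (48)).  The store
built here satisfies that arithmetic with: five content quads in g3
(including the shared triple), a third basis ra7 (g3 references STAT6
directly), reification of four of the five statements, and four
element-level provenance edges.  The domain properties inside content
graphs (hasSubjectDependent, hasRegulatedParticipant, ...) are ex:-
namespaced stand-ins: the domain model is the annotator's choice, not
part of the annotation model.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .reification import (assert_element_provenance, reify_fully,
                          reify_statement)
from .store import AnnotationStore, GraphAnnotation, StoreError
from .vocabulary import Vocab


def _ex(vocab: Vocab, local: str) -> str:
    return vocab.namespaces["ex"] + local


def _obo(vocab: Vocab, local: str) -> str:
    return vocab.namespaces["obo"] + local


def build_syntactic_fixture(vocab: Vocab | None = None) -> AnnotationStore:
    """Token / part-of-speech / dependency-parse example store."""
    store = AnnotationStore(vocab)
    v = store.vocab
    t1, t2 = _ex(v, "t1"), _ex(v, "t2")
    nns, vbp = _ex(v, "NNS"), _ex(v, "VBP")
    dep = _ex(v, "hasSubjectDependent")

    ra1 = store.create_resource_annotation(t1, id=_ex(v, "ra1"))
    ra2 = store.create_resource_annotation(t2, id=_ex(v, "ra2"))
    ra3 = store.create_resource_annotation(nns, id=_ex(v, "ra3"))
    ra4 = store.create_resource_annotation(vbp, id=_ex(v, "ra4"))
    ga1 = store.create_graph_annotation([(t2, dep, t1)], id=_ex(v, "ga1"),
                                        graph_name=_ex(v, "g1"))

    # part-of-speech tagging built on tokenization; the parse on both layers
    store.assert_based_on(ra3.id, ra1.id)
    store.assert_based_on(ra4.id, ra2.id)
    for ra in (ra1, ra2, ra3, ra4):
        store.assert_based_on(ga1.id, ra.id)

    from .reification import reify_element
    s1 = reify_statement(store, ga1, (t2, dep, t1), id=_ex(v, "s1"))
    se1 = reify_element(store, s1, "object", id=_ex(v, "se1"))
    se2 = reify_element(store, s1, "subject", id=_ex(v, "se2"))
    reify_element(store, s1, "property", id=_ex(v, "se3"))
    assert_element_provenance(store, se1, ra1.id)
    assert_element_provenance(store, se2, ra2.id)
    return store


def build_semantic_fixture(vocab: Vocab | None = None) -> AnnotationStore:
    """Biomedical concept-annotation example store (partly reconstructed)."""
    store = AnnotationStore(vocab)
    v = store.vocab
    ipr = _ex(v, "IPR000471")          # interferon (InterPro family)
    pos_reg = _obo(v, "GO_0048518")    # positive regulation of biological process
    neg_reg = _obo(v, "GO_0048519")    # negative regulation of biological process
    stat6 = _obo(v, "PR_000001933")    # STAT6 (Protein Ontology)
    p1, n1 = _ex(v, "P1"), _ex(v, "N1")
    sub = v["subClassOf"]
    regulated = _ex(v, "hasRegulatedParticipant")
    regulator = _ex(v, "hasRegulator")
    reg_process = _ex(v, "hasRegulatedProcess")

    ra5 = store.create_resource_annotation(ipr, id=_ex(v, "ra5"))
    ra6 = store.create_resource_annotation(pos_reg, id=_ex(v, "ra6"))
    ra7 = store.create_resource_annotation(stat6, id=_ex(v, "ra7"))

    shared = (p1, regulated, stat6)  # reused verbatim by g2 and g3
    ga2 = store.create_graph_annotation(
        [(p1, sub, pos_reg), shared],
        id=_ex(v, "ga2"), graph_name=_ex(v, "g2"))
    ga3 = store.create_graph_annotation(
        [(n1, sub, neg_reg), (n1, regulator, ipr), (n1, reg_process, p1),
         (p1, sub, pos_reg), shared],
        id=_ex(v, "ga3"), graph_name=_ex(v, "g3"))

    store.assert_based_on(ga2.id, ra6.id)
    store.assert_based_on(ga2.id, ra7.id)
    store.assert_based_on(ga3.id, ra5.id)
    store.assert_based_on(ga3.id, ga2.id)
    store.assert_based_on(ga3.id, ra7.id)  # reconstructed third basis

    from .reification import reify_element

    def reify_named(ga, triple, sid: str, element_names: tuple[str, str, str]):
        stmt = reify_statement(store, ga, triple, id=_ex(v, sid))
        for position, name in zip(("subject", "property", "object"), element_names):
            reify_element(store, stmt, position, id=_ex(v, name))
        return stmt

    # ga2: both statements fully reified; se4-se6 are the canonical names
    # for the shared statement's elements, the rest continue the numbering
    s4 = reify_named(ga2, (p1, sub, pos_reg), "s4", ("se10", "se11", "se12"))
    s2 = reify_named(ga2, shared, "s2", ("se4", "se5", "se6"))
    se6 = store.elements[s2.elements["object"]]
    assert_element_provenance(store, store.elements[s4.elements["object"]], ra6.id)
    assert_element_provenance(store, se6, ra7.id)

    # ga3: four of five statements reified (the N1 typing statement is not),
    # with four element-level provenance edges — a reconstruction satisfying
    # the published 32 (48) count
    s5 = reify_named(ga3, (n1, regulator, ipr), "s5", ("se13", "se14", "se15"))
    s6 = reify_named(ga3, (n1, reg_process, p1), "s6", ("se16", "se17", "se18"))
    s7 = reify_named(ga3, (p1, sub, pos_reg), "s7", ("se19", "se20", "se21"))
    s3 = reify_named(ga3, shared, "s3", ("se7", "se8", "se9"))
    se9 = store.elements[s3.elements["object"]]
    assert_element_provenance(store, store.elements[s5.elements["object"]], ra5.id)
    assert_element_provenance(store, store.elements[s6.elements["object"]],
                              s2.elements["subject"])
    assert_element_provenance(store, store.elements[s7.elements["object"]],
                              s4.elements["object"])
    assert_element_provenance(store, se9, se6.id)
    return store


# -- synthetic stacks ------------------------------------------------------

@dataclass(frozen=True)
class StackSpec:
    """Shape of a layered synthetic annotation stack.

    Emulates pipelines in which each stage annotates on top of earlier
    stages' output: annotations in layer k may only be based on layers
    below k, so stacks are acyclic by construction.  Defaults give a
    small three-stage pipeline of mixed resource and graph annotations
    with element-level provenance on half the reified elements —
    roughly the density of the worked examples.
    """

    layers: int = 3
    annotations_per_layer: int = 4
    graph_fraction: float = 0.5
    bases_per_annotation: int = 2
    element_provenance_rate: float = 0.5
    max_statements: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.layers < 1 or self.annotations_per_layer < 1:
            raise StoreError("layers and annotations_per_layer must be >= 1")
        for rate in (self.graph_fraction, self.element_provenance_rate):
            if not 0.0 <= rate <= 1.0:
                raise StoreError("proportions must lie in [0, 1]")
        if self.bases_per_annotation < 0 or self.max_statements < 1:
            raise StoreError("bases_per_annotation >= 0 and max_statements >= 1")


def generate_stack(spec: StackSpec, vocab: Vocab | None = None) -> AnnotationStore:
    """Deterministic, model-conformant store for a stack specification."""
    rng = random.Random(spec.seed)
    store = AnnotationStore(vocab)
    v = store.vocab
    concept = lambda i: _ex(v, f"c{i}")  # noqa: E731 - tiny local factory
    n_concepts = max(8, spec.annotations_per_layer * spec.layers)

    previous: list[str] = []       # annotation ids in earlier layers
    previous_elements: list[str] = []
    for layer in range(spec.layers):
        current: list[str] = []
        current_elements: list[str] = []
        for _ in range(spec.annotations_per_layer):
            if rng.random() < spec.graph_fraction:
                n_stmts = rng.randint(1, spec.max_statements)
                triples = set()
                while len(triples) < n_stmts:
                    triples.add((concept(rng.randrange(n_concepts)),
                                 _ex(v, f"p{rng.randrange(4)}"),
                                 concept(rng.randrange(n_concepts))))
                ann: GraphAnnotation = store.create_graph_annotation(sorted(triples))
                for triple in sorted(triples):
                    stmt = reify_fully(store, ann, triple)
                    for el_id in stmt.elements.values():
                        if previous and rng.random() < spec.element_provenance_rate:
                            basis = rng.choice(sorted(previous + previous_elements))
                            if basis != el_id:
                                assert_element_provenance(store, el_id, basis)
                        current_elements.append(el_id)
            else:
                ann = store.create_resource_annotation(
                    concept(rng.randrange(n_concepts)))
            if previous and spec.bases_per_annotation:
                k = min(spec.bases_per_annotation, len(previous))
                for basis in rng.sample(sorted(previous), k):
                    store.assert_based_on(ann.id, basis)
            current.append(ann.id)
        previous += current
        previous_elements += current_elements
    return store
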