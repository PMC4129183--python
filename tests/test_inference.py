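import json

import pytest

from kiao.fixtures import StackSpec, generate_stack
from kiao.inference import (infer_has_part, infer_types, validate,
                            violations_as_jsonl)
from kiao.store import AnnotationStore, Quad, Term

from conftest import ex, has_part_closure_oracle


class TestInferHasPart:
    def test_ga1_gains_parts_for_all_three_elements(self, syntactic):
        inferred = infer_has_part(syntactic)
        pairs = {(q.subject.value, q.obj.value) for q in inferred}
        ga1 = ex(syntactic, "ga1")
        assert pairs == {(ga1, ex(syntactic, f"se{i}")) for i in (1, 2, 3)}

    def test_empty_store_yields_nothing(self, vocab):
        assert infer_has_part(AnnotationStore(vocab)) == set()

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_naive_closure_oracle(self, seed):
        store = generate_stack(StackSpec(layers=2, annotations_per_layer=3,
                                         seed=seed))
        inferred = {(q.subject.value, q.obj.value)
                    for q in infer_has_part(store)}
        assert inferred == has_part_closure_oracle(store)

    def test_monotone_under_added_quads(self, syntactic):
        base = infer_has_part(syntactic)
        triple = (ex(syntactic, "x"), ex(syntactic, "p"), ex(syntactic, "y"))
        ga = syntactic.create_graph_annotation([triple])
        from kiao.reification import reify_fully
        reify_fully(syntactic, ga, triple)
        assert base <= infer_has_part(syntactic)

    def test_inferred_quads_live_outside_content_graphs(self, semantic):
        content = {a.graph_name for a in semantic.annotations.values()
                   if hasattr(a, "graph_name")}
        for quad in infer_has_part(semantic) | infer_types(semantic):
            assert quad.graph not in content
            assert quad.graph is not None


class TestInferTypes:
    def test_element_link_entails_domain_and_range_types(self, vocab):
        store = AnnotationStore(vocab)
        triple = (ex(store, "a"), ex(store, "p"), ex(store, "b"))
        ga = store.create_graph_annotation([triple])
        from kiao.reification import reify_fully
        stmt = reify_fully(store, ga, triple)
        inferred = {(q.subject.value, q.obj.value) for q in infer_types(store)}
        assert (stmt.id, vocab["RdfStatement"]) in inferred
        for el_id in stmt.elements.values():
            assert (el_id, vocab["RdfStatementElement"]) in inferred

    def test_empty_store_yields_nothing(self, vocab):
        assert infer_types(AnnotationStore(vocab)) == set()

    @pytest.mark.parametrize("fixture", ["syntactic", "semantic"])
    def test_inferred_subset_of_materialized_types(self, fixture, request):
        """The builders materialize every inferable type quad, so RDFS
        domain/range reasoning rediscovers a subset of the stored set."""
        store = request.getfixturevalue(fixture)
        stored = {(q.subject.value, q.obj.value)
                  for q in store.quads
                  if q.graph is None and q.predicate.value == store.vocab["type"]}
        inferred = {(q.subject.value, q.obj.value) for q in infer_types(store)}
        assert inferred <= stored

    def test_idempotent_fixpoint(self, semantic):
        """Re-running inference over store + inferences adds nothing new."""
        first = infer_has_part(semantic) | infer_types(semantic)
        clone = semantic.copy()
        for quad in first:
            clone.add_extra_quad(quad)
        assert (infer_has_part(clone) | infer_types(clone)) == first


class TestValidate:
    def test_worked_examples_are_clean(self, syntactic, semantic):
        assert validate(syntactic) == []
        assert validate(semantic) == []

    def test_violations_serialize_as_json_lines(self, syntactic):
        denotes = Term.iri(syntactic.vocab["denotes"])
        quad = next(syntactic.match(Term.iri(ex(syntactic, "ra1")), denotes))
        syntactic.remove_quad(quad)
        report = violations_as_jsonl(validate(syntactic))
        parsed = [json.loads(line) for line in report.splitlines()]
        assert any(v["code"] == "multi-denotation" for v in parsed)

    # one corruption per invariant class; each must be caught
    def test_deleted_denotes_caught(self, syntactic):
        quad = next(syntactic.match(Term.iri(ex(syntactic, "ga1")),
                                    Term.iri(syntactic.vocab["denotes"])))
        syntactic.remove_quad(quad)
        assert {"multi-denotation"} <= {v.code for v in validate(syntactic)}

    def test_duplicate_denotes_caught(self, syntactic):
        syntactic._add(Quad(Term.iri(ex(syntactic, "ra1")),
                            Term.iri(syntactic.vocab["denotes"]),
                            Term.iri(ex(syntactic, "t2"))))
        assert {"multi-denotation"} <= {v.code for v in validate(syntactic)}

    def test_emptied_content_graph_caught(self, syntactic):
        ga = syntactic.annotations[ex(syntactic, "ga1")]
        for quad in list(syntactic.quads):
            if quad.graph == ga.graph_name:
                syntactic.remove_quad(quad)
        codes = {v.code for v in validate(syntactic)}
        assert "empty-graph-annotation" in codes

    def test_element_source_mismatch_caught(self, syntactic):
        se1 = ex(syntactic, "se1")
        denotes = Term.iri(syntactic.vocab["denotes"])
        quad = next(syntactic.match(Term.iri(se1), denotes))
        syntactic.remove_quad(quad)
        syntactic._add(Quad(Term.iri(se1), denotes,
                            Term.iri(ex(syntactic, "VBP"))))
        assert {"element-source-mismatch"} <= {v.code for v in validate(syntactic)}

    def test_orphan_element_caught(self, syntactic):
        link = Term.iri(syntactic.vocab["objectElement"])
        quad = next(syntactic.match(None, link))
        syntactic.remove_quad(quad)
        assert {"orphan-element"} <= {v.code for v in validate(syntactic)}

    def test_dangling_based_on_caught(self, syntactic):
        syntactic._add(Quad(Term.iri(ex(syntactic, "ga1")),
                            Term.iri(syntactic.vocab["basedOn"]),
                            Term.iri(ex(syntactic, "ghost"))))
        assert {"dangling-based-on"} <= {v.code for v in validate(syntactic)}

    def test_cycle_reported_as_warning(self, syntactic):
        v = syntactic.vocab
        based_on = Term.iri(v["basedOn"])
        syntactic._add(Quad(Term.iri(ex(syntactic, "ra1")), based_on,
                            Term.iri(ex(syntactic, "ra3"))))
        findings = validate(syntactic)
        cycle = [f for f in findings if f.code == "based-on-cycle"]
        assert cycle and all(f.severity == "warning" for f in cycle)

    def test_literal_element_flagged_as_warning(self, vocab):
        store = AnnotationStore(vocab)
        triple = (Term.iri(ex(store, "a")), Term.iri(ex(store, "p")),
                  Term.literal("leaf"))
        ga = store.create_graph_annotation([triple])
        from kiao.reification import reify_fully
        reify_fully(store, ga, triple)
        flagged = [f for f in validate(store) if f.code == "literal-element"]
        assert flagged and all(f.severity == "warning" for f in flagged)
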