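import pytest

from kiao.fixtures import StackSpec, generate_stack
from kiao.query import (load_query, retraction_set, sparql_annotations_based_on,
                        sparql_statements_based_on, statements_based_on,
                        trace_downstream, trace_upstream)
from kiao.store import StoreError

from conftest import ex, reachable_by_paths, reverse_reachable_by_paths


class TestTraceDownstream:
    def test_annotations_based_on_ra7(self, semantic):
        result = trace_downstream(semantic, ex(semantic, "ra7"), "annotation")
        assert result == {ex(semantic, "ga2"), ex(semantic, "ga3")}

    def test_mixed_granularity_includes_elements(self, semantic):
        result = trace_downstream(semantic, ex(semantic, "ra7"))
        assert {ex(semantic, "se6"), ex(semantic, "se9")} <= result

    def test_leaf_has_no_dependents(self, semantic):
        assert trace_downstream(semantic, ex(semantic, "ga3")) == set()

    def test_unknown_basis_rejected(self, semantic):
        with pytest.raises(StoreError):
            trace_downstream(semantic, ex(semantic, "nothing"))

    def test_reflexive_flag_adds_the_basis(self, semantic):
        ra7 = ex(semantic, "ra7")
        assert ra7 in trace_downstream(semantic, ra7, reflexive=True)
        assert ra7 not in trace_downstream(semantic, ra7)


class TestTraceUpstream:
    def test_ga1_bases_are_the_four_resource_annotations(self, syntactic):
        result = trace_upstream(syntactic, ex(syntactic, "ga1"), "annotation")
        assert result == {ex(syntactic, f"ra{i}") for i in (1, 2, 3, 4)}

    def test_leaf_annotation_has_empty_upstream(self, syntactic):
        assert trace_upstream(syntactic, ex(syntactic, "ra1")) == set()

    def test_chain_through_ga2(self, semantic):
        result = trace_upstream(semantic, ex(semantic, "ga3"), "annotation")
        # ga3 -> {ra5, ga2, ra7}, and through ga2 -> {ra6, ra7}
        assert result == {ex(semantic, n) for n in ("ra5", "ga2", "ra6", "ra7")}


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", range(10))
    def test_closures_match_path_enumeration(self, seed):
        store = generate_stack(StackSpec(seed=seed))
        edges = store.based_on_edges()
        for node in sorted(store.known_ices()):
            assert trace_upstream(store, node) == reachable_by_paths(edges, node)
            assert trace_downstream(store, node) == \
                reverse_reachable_by_paths(edges, node)

    @pytest.mark.parametrize("seed", range(5))
    def test_up_and_down_are_mutually_consistent(self, seed):
        store = generate_stack(StackSpec(layers=2, annotations_per_layer=3,
                                         seed=seed))
        nodes = sorted(store.known_ices())
        for x in nodes:
            for y in trace_upstream(store, x):
                assert x in trace_downstream(store, y)

    @pytest.mark.parametrize("seed", range(5))
    def test_statements_based_on_matches_exhaustive_scan(self, seed):
        store = generate_stack(StackSpec(seed=seed, element_provenance_rate=0.8))
        edges = store.based_on_edges()
        for basis in sorted(store.annotations):
            expected = {
                stmt.id for stmt in store.statements.values()
                if any(basis in reachable_by_paths(edges, el_id)
                       for el_id in stmt.elements.values())
            }
            assert statements_based_on(store, basis) == expected


class TestStatementsBasedOn:
    def test_ra7_reaches_both_shared_statement_reifications(self, semantic):
        result = statements_based_on(semantic, ex(semantic, "ra7"))
        assert result == {ex(semantic, "s2"), ex(semantic, "s3")}

    def test_unreferenced_basis_yields_nothing(self, syntactic):
        assert statements_based_on(syntactic, ex(syntactic, "ra3")) == set()


class TestRetractionSet:
    def test_dependencies_precede_dependents(self, semantic):
        order = retraction_set(semantic, ex(semantic, "ra7"))
        assert order.index(ex(semantic, "ga2")) < order.index(ex(semantic, "ga3"))
        assert order.index(ex(semantic, "se6")) < order.index(ex(semantic, "se9"))

    def test_isolated_annotation_retracts_alone(self, vocab):
        from kiao.store import AnnotationStore
        store = AnnotationStore(vocab)
        ra = store.create_resource_annotation(ex(store, "t1"))
        assert retraction_set(store, ra.id) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_order_respects_every_based_on_edge(self, seed):
        store = generate_stack(StackSpec(seed=seed))
        edges = store.based_on_edges()
        for basis in sorted(store.annotations):
            order = retraction_set(store, basis)
            position = {ice: i for i, ice in enumerate(order)}
            for subject, obj in edges:
                if subject in position and obj in position:
                    assert position[obj] < position[subject]

    def test_cycle_falls_back_to_sorted_order_with_warning(self, vocab):
        import warnings as w

        from kiao.store import AnnotationStore
        store = AnnotationStore(vocab)
        a = store.create_resource_annotation(ex(store, "t1"))
        b = store.create_resource_annotation(ex(store, "t2"))
        c = store.create_resource_annotation(ex(store, "t3"))
        store.assert_based_on(a.id, c.id)
        store.assert_based_on(b.id, a.id)
        with w.catch_warnings():
            w.simplefilter("ignore")
            store.assert_based_on(a.id, b.id)  # closes a <-> b cycle
        with pytest.warns(UserWarning):
            assert retraction_set(store, c.id) == sorted([a.id, b.id])


class TestSparqlEquivalence:
    def test_shipped_queries_are_property_path_sparql(self):
        assert "kiao:basedOn+" in load_query("annotations_based_on")
        assert "kiao:subjectElement|kiao:propertyElement|kiao:objectElement" \
            in load_query("statements_based_on")

    def test_annotation_query_agrees_with_library_tracing(self, semantic):
        for basis in ("ra7", "ra6", "ga2"):
            iri = ex(semantic, basis)
            assert sparql_annotations_based_on(semantic, iri) == \
                trace_downstream(semantic, iri, "annotation")

    def test_statement_query_agrees_with_library_tracing(self, semantic):
        for basis in ("ra7", "ra5", "ra6"):
            iri = ex(semantic, basis)
            assert sparql_statements_based_on(semantic, iri) == \
                statements_based_on(semantic, iri)

    @pytest.mark.parametrize("seed", range(3))
    def test_engine_equivalence_on_random_stacks(self, seed):
        store = generate_stack(StackSpec(layers=2, annotations_per_layer=3,
                                         seed=seed, element_provenance_rate=0.7))
        for basis in sorted(store.annotations):
            assert sparql_annotations_based_on(store, basis) == \
                trace_downstream(store, basis, "annotation")
            assert sparql_statements_based_on(store, basis) == \
                statements_based_on(store, basis)
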