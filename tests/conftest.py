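import pytest

from kiao import build_semantic_fixture, build_syntactic_fixture
from kiao.vocabulary import Vocab


@pytest.fixture
def vocab() -> Vocab:
    return Vocab()


@pytest.fixture
def syntactic(vocab):
    """Token/POS/dependency-parse worked example."""
    return build_syntactic_fixture(vocab)


@pytest.fixture
def semantic(vocab):
    """Biomedical concept-annotation worked example."""
    return build_semantic_fixture(vocab)


def ex(store, local: str) -> str:
    return store.vocab.expand(f"ex:{local}")


# -- independent oracles ---------------------------------------------------

def reachable_by_paths(edges: set[tuple[str, str]], start: str) -> set[str]:
    """Brute-force path enumeration forward from ``start`` (x -> y edges)."""
    found: set[str] = set()
    frontier = [start]
    while frontier:
        node = frontier.pop()
        for s, o in edges:
            if s == node and o not in found:
                found.add(o)
                frontier.append(o)
    return found


def reverse_reachable_by_paths(edges: set[tuple[str, str]], start: str) -> set[str]:
    return reachable_by_paths({(o, s) for s, o in edges}, start)


def has_part_closure_oracle(store) -> set[tuple[str, str]]:
    """Naive transitive closure of has_part + element-link edges,
    restricted to annotation -> element pairs."""
    v = store.vocab
    part_props = {v["has_part"], *v.element_link_properties()}
    relation = {(q.subject.value, q.obj.value)
                for q in store.quads
                if q.graph is None and q.predicate.value in part_props
                and not q.obj.is_literal}
    closure = set(relation)
    while True:
        extra = {(a, c) for a, b in closure for b2, c in relation if b == b2}
        if extra <= closure:
            break
        closure |= extra
    return {(a, b) for a, b in closure
            if a in store.annotations and b in store.elements}
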