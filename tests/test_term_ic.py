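"""Information-content table, MICA, Jiang-Conrath/Rel similarities, BMA."""

import math

import numpy as np
import pytest

from gosimnet.ontology import AnnotationSet, OntologyGraph, Term
from gosimnet.term_ic import (
    bma,
    compute_ic_table,
    make_termsim,
    mica,
    sim_jc,
    sim_rel,
)

from conftest import make_chain_ontology

A, B, C = "GO:0000001", "GO:0000002", "GO:0000003"


def random_dag_with_annotations(seed, n_terms=30, n_proteins=20):
    """Random layered DAG + random annotations, for oracle comparison."""
    rng = np.random.default_rng(seed)
    onto = OntologyGraph()
    ids = [f"GO:{i:07d}" for i in range(1, n_terms + 1)]
    for t in ids:
        onto.terms[t] = Term(id=t, namespace="biological_process")
    for i in range(1, n_terms):
        # parents only among lower-indexed terms: acyclic by construction
        for p in rng.choice(i, size=min(i, int(rng.integers(1, 3))), replace=False):
            onto.relations.add((ids[i], ids[p], "is_a"))
    ann = {}
    for j in range(n_proteins):
        k = int(rng.integers(1, 4))
        terms = rng.choice(n_terms, size=k, replace=False)
        ann[f"P{j:03d}"] = frozenset(ids[t] for t in terms)
    return onto, AnnotationSet(annotations=ann)


def brute_force_p(onto, annotations):
    """Oracle: explicit descendant enumeration per term, then protein counting."""
    children = {}
    for child, parent, _ in onto.relations:
        children.setdefault(parent, set()).add(child)

    def descendants(t):
        out, stack = {t}, [t]
        while stack:
            for c in children.get(stack.pop(), ()):
                if c not in out:
                    out.add(c)
                    stack.append(c)
        return out

    N = len(annotations.annotations)
    p = {}
    for t in onto.terms:
        ds = descendants(t)
        count = sum(1 for terms in annotations.annotations.values() if terms & ds)
        p[t] = count / N
    return p


class TestICTable:
    def test_worked_frequency_example(self):
        """10 of 50 annotated proteins under term g gives p(g) = 0.2, ic = -log 0.2."""
        onto = OntologyGraph()
        onto.terms["GO:0000001"] = Term(id="GO:0000001", namespace="biological_process")
        ann = {f"P{i}": frozenset({"GO:0000001"}) for i in range(10)}
        # 40 proteins annotated elsewhere
        onto.terms["GO:0000002"] = Term(id="GO:0000002", namespace="biological_process")
        for i in range(10, 50):
            ann[f"P{i}"] = frozenset({"GO:0000002"})
        table = compute_ic_table(onto, AnnotationSet(annotations=ann))
        assert table.N == 50
        assert table.p["GO:0000001"] == pytest.approx(0.2)
        assert table.ic["GO:0000001"] == pytest.approx(-math.log(0.2))

    def test_chain_propagation(self, chain_ontology):
        """One protein on the leaf propagates p=1 to every ancestor."""
        ann = AnnotationSet(annotations={"P1": frozenset({C})})
        table = compute_ic_table(chain_ontology, ann)
        assert table.p == {A: 1.0, B: 1.0, C: 1.0}
        assert table.ic[A] == 0.0

    def test_chain_frequencies(self, chain_ontology, chain_annotations):
        table = compute_ic_table(chain_ontology, chain_annotations)
        assert table.p[A] == pytest.approx(1.0)
        assert table.p[B] == pytest.approx(0.5)
        assert table.p[C] == pytest.approx(0.25)

    def test_zero_frequency_term_gets_infinite_ic(self, chain_ontology):
        ann = AnnotationSet(annotations={"P1": frozenset({B})})
        table = compute_ic_table(chain_ontology, ann)
        assert table.p[C] == 0.0
        assert math.isinf(table.ic[C])

    def test_cycle_rejected(self, chain_ontology):
        chain_ontology.relations.add((A, C, "is_a"))
        ann = AnnotationSet(annotations={"P1": frozenset({C})})
        with pytest.raises(ValueError, match="cycle"):
            compute_ic_table(chain_ontology, ann)

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_brute_force_oracle(self, seed):
        onto, ann = random_dag_with_annotations(seed)
        table = compute_ic_table(onto, ann)
        oracle = brute_force_p(onto, ann)
        for t in onto.terms:
            assert table.p[t] == pytest.approx(oracle[t], abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_monotone_along_relations(self, seed):
        """p never decreases and ic never increases from child to parent."""
        onto, ann = random_dag_with_annotations(seed, n_terms=40)
        table = compute_ic_table(onto, ann)
        for child, parent, _ in onto.relations:
            assert table.p[parent] >= table.p[child]
            assert table.ic[parent] <= table.ic[child]


class TestMica:
    def test_self_mica(self, chain_ontology, chain_annotations):
        table = compute_ic_table(chain_ontology, chain_annotations)
        assert mica(C, C, chain_ontology, table) == C

    def test_chain_mica_is_deeper_term(self, chain_ontology, chain_annotations):
        table = compute_ic_table(chain_ontology, chain_annotations)
        assert mica(C, B, chain_ontology, table) == B

    def test_siblings_meet_at_parent(self):
        onto = make_chain_ontology()
        onto.terms["GO:0000004"] = Term(id="GO:0000004", namespace="molecular_function")
        onto.relations.add(("GO:0000004", B, "is_a"))  # sibling of C under B
        ann = AnnotationSet(
            annotations={
                "P1": frozenset({C}),
                "P2": frozenset({"GO:0000004"}),
                "P3": frozenset({A}),
            }
        )
        table = compute_ic_table(onto, ann)
        assert mica(C, "GO:0000004", onto, table) == B

    def test_disconnected_terms_have_no_mica(self):
        onto = OntologyGraph()
        for t in ("GO:0000001", "GO:0000002"):
            onto.terms[t] = Term(id=t, namespace="biological_process")
        ann = AnnotationSet(
            annotations={"P1": frozenset({"GO:0000001"}), "P2": frozenset({"GO:0000002"})}
        )
        table = compute_ic_table(onto, ann)
        assert mica("GO:0000001", "GO:0000002", onto, table) is None


class TestSimJC:
    def test_identity_is_zero(self, chain_ontology, chain_annotations):
        table = compute_ic_table(chain_ontology, chain_annotations)
        assert sim_jc(C, C, chain_ontology, table) == pytest.approx(0.0)

    def test_chain_closed_form(self, chain_ontology, chain_annotations):
        # sim_jc(C,B) = ic(B) - ic(C) = log(1/2) - log(1/4) scaled = -log 2
        table = compute_ic_table(chain_ontology, chain_annotations)
        assert sim_jc(C, B, chain_ontology, table) == pytest.approx(-math.log(2))

    def test_always_nonpositive(self):
        for seed in range(3):
            onto, ann = random_dag_with_annotations(seed)
            table = compute_ic_table(onto, ann)
            fn = make_termsim(onto, table, method="jc")
            terms = sorted(onto.terms)
            for a in terms[:10]:
                for b in terms[:10]:
                    s = fn(a, b)
                    if s is not None:
                        assert s <= 1e-12

    def test_infinite_ic_undefined(self, chain_ontology):
        ann = AnnotationSet(annotations={"P1": frozenset({B})})
        table = compute_ic_table(chain_ontology, ann)
        assert sim_jc(C, B, chain_ontology, table) is None


class TestSimRel:
    def test_identity_reduces_to_one_minus_p(self):
        """sim_rel(g,g) = 1 - p(g): 0.8 at the worked frequency p = 0.2."""
        onto = OntologyGraph()
        onto.terms["GO:0000001"] = Term(id="GO:0000001", namespace="biological_process")
        onto.terms["GO:0000002"] = Term(id="GO:0000002", namespace="biological_process")
        ann = {f"P{i}": frozenset({"GO:0000001"}) for i in range(10)}
        for i in range(10, 50):
            ann[f"P{i}"] = frozenset({"GO:0000002"})
        table = compute_ic_table(onto, AnnotationSet(annotations=ann))
        assert sim_rel("GO:0000001", "GO:0000001", onto, table) == pytest.approx(0.8)

    def test_root_mica_gives_zero(self, chain_ontology, chain_annotations):
        """Terms meeting only at the root (p=1) share nothing informative."""
        onto = make_chain_ontology()
        onto.terms["GO:0000005"] = Term(id="GO:0000005", namespace="molecular_function")
        onto.relations.add(("GO:0000005", A, "is_a"))
        ann = AnnotationSet(
            annotations={
                "P1": frozenset({C}),
                "P2": frozenset({"GO:0000005"}),
            }
        )
        table = compute_ic_table(onto, ann)
        assert sim_rel(C, "GO:0000005", onto, table) == pytest.approx(0.0)

    def test_chain_closed_form(self, chain_ontology, chain_annotations):
        # (2 log2 / (log2 + log4)) * (1 - 1/2) = 1/3
        table = compute_ic_table(chain_ontology, chain_annotations)
        assert sim_rel(C, B, chain_ontology, table) == pytest.approx(1 / 3)

    def test_range(self):
        for seed in range(3):
            onto, ann = random_dag_with_annotations(seed)
            table = compute_ic_table(onto, ann)
            fn = make_termsim(onto, table, method="rel")
            terms = sorted(onto.terms)
            for a in terms[:10]:
                for b in terms[:10]:
                    s = fn(a, b)
                    if s is not None:
                        assert 0.0 <= s < 1.0

    def test_additive_variant_available(self, chain_ontology, chain_annotations):
        table = compute_ic_table(chain_ontology, chain_annotations)
        mult = sim_rel(C, B, chain_ontology, table)
        add = sim_rel(C, B, chain_ontology, table, additive=True)
        assert add == pytest.approx(2 / 3 + 1 / 2)
        assert add != mult


class TestBMA:
    def test_single_term_pair_reduces_to_termsim(self, chain_ontology, chain_annotations):
        table = compute_ic_table(chain_ontology, chain_annotations)
        fn = make_termsim(chain_ontology, table, method="rel")
        ann = AnnotationSet(
            annotations={"Pm": frozenset({C}), "Pn": frozenset({B})}
        )
        assert bma("Pm", "Pn", ann, fn) == pytest.approx(fn(C, B))

    def test_hand_evaluated_average(self):
        sims = {("a", "b"): 0.9, ("a", "c"): 0.1}

        def fn(x, y):
            return sims.get((x, y), sims.get((y, x)))

        ann = AnnotationSet(
            annotations={"Pm": frozenset({"a"}), "Pn": frozenset({"b", "c"})}
        )
        assert bma("Pm", "Pn", ann, fn) == pytest.approx(0.7)

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        terms = list("abcdef")
        sims = {}
        for i, x in enumerate(terms):
            for y in terms[i:]:
                sims[(x, y)] = float(rng.random())

        def fn(x, y):
            return sims.get((x, y), sims.get((y, x)))

        ann = AnnotationSet(
            annotations={
                "Pm": frozenset({"a", "b", "c"}),
                "Pn": frozenset({"d", "e"}),
            }
        )
        assert bma("Pm", "Pn", ann, fn) == pytest.approx(bma("Pn", "Pm", ann, fn))

    def test_undefined_pairs_skipped_and_all_undefined_is_none(self):
        def fn(x, y):
            return None

        ann = AnnotationSet(
            annotations={"Pm": frozenset({"a"}), "Pn": frozenset({"b"})}
        )
        assert bma("Pm", "Pn", ann, fn) is None
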