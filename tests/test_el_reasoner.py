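"""Normalization, saturation and taxonomy construction."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seponto.core_model import (
    ConceptRef,
    Named,
    Ontology,
    Role,
    UnknownIdError,
    conj,
    equivalent,
    some,
    subclass_of,
)
from seponto.el_reasoner import (
    classify,
    entails,
    fresh_name,
    is_fresh,
    normalize,
    saturate,
)
from seponto.synthetic import GenConfig, generate, naive_closure


def small_ontology(*concept_ids, roles=()):
    ont = Ontology()
    for cid in concept_ids:
        ont.add_concept(ConceptRef(id=cid, fsn=f"{cid} (test)"))
    for r in roles:
        ont.add_role(r)
    return ont


class TestNormalize:
    def test_atomic_axiom_passes_through(self):
        ont = small_ontology("A", "B")
        ont.add_axiom(subclass_of("A", "B"))
        n = normalize(ont)
        assert n.atomic == {("A", "B")}
        assert n.rule_count() == 1 and not n.fresh

    def test_equivalence_splits_into_both_directions(self):
        ont = small_ontology("S", "E", roles=[Role("aopo", "all or part of")])
        ont.add_axiom(equivalent("S", some("aopo", "E")))
        n = normalize(ont)
        assert ("S", "aopo", "E") in n.exist_right
        assert ("aopo", "E", "S") in n.exist_left
        assert n.rule_count() == 2

    def test_defined_conjunction_normalizes_to_four_rules_one_fresh(self):
        # A ≡ B ⊓ ∃r.C by hand:
        #   A ⊑ B;  A ⊑ ∃r.C;  ∃r.C ⊑ N;  {B, N} ⊑ A   — one fresh name N
        ont = small_ontology("A", "B", "C", roles=[Role("r", "r")])
        ont.add_axiom(equivalent("A", conj(Named("B"), some("r", "C"))))
        n = normalize(ont)
        assert n.rule_count() == 4
        assert len(n.fresh) == 1
        (fresh,) = n.fresh
        assert n.atomic == {("A", "B")}
        assert n.exist_right == {("A", "r", "C")}
        assert n.exist_left == {("r", "C", fresh)}
        assert n.conjunctions == {(frozenset({"B", fresh}), "A")}

    def test_fresh_names_are_deterministic(self):
        expr = some("r", conj(Named("B"), Named("C")))
        assert fresh_name(expr) == fresh_name(some("r", conj(Named("C"), Named("B"))))
        assert is_fresh(fresh_name(expr))


class TestSaturate:
    def test_empty_axiom_set_closure_is_reflexive_only(self):
        ont = small_ontology("A", "B")
        tax = classify(ont)
        assert tax.closure == frozenset({("A", "A"), ("B", "B")})

    def test_role_hierarchy_lifts_edges(self):
        ont = small_ontology(
            "A", "B", "S",
            roles=[Role("aopo", "all or part of"),
                   Role("rpo", "regional part of", parent="aopo")],
        )
        ont.add_axiom(subclass_of("A", some("rpo", "B")))
        ont.add_axiom(equivalent("S", some("aopo", "B")))
        assert classify(ont).contains("A", "S")

    def test_transitivity_is_compiled_to_a_chain(self):
        ont = small_ontology(
            "A", "B", "C", "S",
            roles=[Role("p", "part of", transitive=True)],
        )
        ont.add_axiom(subclass_of("A", some("p", "B")))
        ont.add_axiom(subclass_of("B", some("p", "C")))
        ont.add_axiom(equivalent("S", some("p", "C")))
        assert classify(ont).contains("A", "S")

    def test_explicit_role_chain(self):
        from seponto.core_model import RoleChain

        ont = small_ontology(
            "A", "B", "C", "T",
            roles=[Role("r", "r"), Role("s", "s"), Role("t", "t")],
        )
        ont.add_chain(RoleChain(("r", "s"), "t"))
        ont.add_axiom(subclass_of("A", some("r", "B")))
        ont.add_axiom(subclass_of("B", some("s", "C")))
        ont.add_axiom(equivalent("T", some("t", "C")))
        assert classify(ont).contains("A", "T")


class TestTaxonomy:
    def test_classification_is_idempotent(self, trunk):
        t1 = classify(trunk.ontology)
        t2 = classify(trunk.ontology)
        assert t1 == t2

    def test_direct_parent_map_reconstructs_closure(self, trunk_taxonomy):
        assert trunk_taxonomy.reclosed() == trunk_taxonomy.closure

    def test_fresh_names_excluded_from_outputs(self, trunk_taxonomy):
        for a, b in trunk_taxonomy.closure:
            assert not is_fresh(a) and not is_fresh(b)

    def test_equivalent_concepts_grouped_with_least_representative(self):
        ont = small_ontology("b", "a", "c")
        ont.add_axiom(subclass_of("a", "b"))
        ont.add_axiom(subclass_of("b", "a"))
        ont.add_axiom(subclass_of("c", "a"))
        tax = classify(ont)
        assert ("a", "b") in tax.equivalence_classes
        assert tax.representative["b"] == "a"
        assert tax.direct_parents("c") == ("a",)

    def test_single_concept_ontology_is_a_one_root_taxonomy(self):
        tax = classify(small_ontology("A"))
        assert tax.closure == frozenset({("A", "A")})
        assert tax.direct == {"A": ()}

    def test_entails_rejects_unknown_ids(self):
        ont = small_ontology("A")
        with pytest.raises(UnknownIdError):
            entails(ont, "A", "nope")
        assert entails(ont, "A", "A")


class TestAgainstOracle:
    @settings(max_examples=150)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_closure_matches_naive_oracle_on_random_ontologies(self, seed):
        """Soundness and completeness against the canonical-model oracle."""
        rng = random.Random(seed)
        cfg = GenConfig(
            n_concepts=rng.randint(2, 12),
            n_roles=rng.randint(0, 3),
            n_axioms=rng.randint(1, 18),
            seed=seed,
        )
        ont = generate(cfg)
        assert classify(ont).closure == naive_closure(ont)

    @settings(max_examples=60)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_adding_an_axiom_never_removes_entailments(self, seed):
        rng = random.Random(seed)
        ont = generate(GenConfig(n_concepts=8, n_roles=2, n_axioms=10, seed=seed))
        before = classify(ont).closure
        a, b = rng.sample(sorted(ont.concepts), 2)
        ont.add_axiom(subclass_of(a, b))
        assert before <= classify(ont).closure
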