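"""Ontology assembly invariants: ids, synonyms, axioms, structural equality."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from seponto.core_model import (
    Axiom,
    AxiomKind,
    ConceptRef,
    Conjunction,
    DuplicateIdError,
    DuplicateSynonymError,
    Existential,
    Named,
    Ontology,
    OntologyError,
    Role,
    UnknownIdError,
    canonical,
    conj,
    equivalent,
    some,
    subclass_of,
)


def concept(cid, fsn=None, preferred=""):
    return ConceptRef(id=cid, fsn=fsn or f"{cid} (body structure)",
                      preferred_term=preferred)


class TestConceptDeclaration:
    def test_single_concept_with_abdomen_term(self):
        ont = Ontology()
        ont.add_concept(concept("818983003", preferred="Abdomen"))
        assert len(ont.concepts) == 1
        assert ont.concept("818983003").preferred_term == "Abdomen"

    def test_duplicate_id_rejected_naming_the_id(self):
        ont = Ontology().add_concept(concept("818983003"))
        with pytest.raises(DuplicateIdError, match="818983003"):
            ont.add_concept(concept("818983003"))

    def test_second_abdomen_preferred_term_rejected_naming_both(self):
        ont = Ontology()
        ont.add_concept(concept("818983003", preferred="Abdomen"))
        with pytest.raises(DuplicateSynonymError) as exc:
            ont.add_concept(concept("X-other", preferred="Abdomen"))
        assert "818983003" in str(exc.value) and "X-other" in str(exc.value)

    def test_duplicate_fsn_rejected(self):
        ont = Ontology().add_concept(concept("a", fsn="Liver structure (body structure)"))
        with pytest.raises(DuplicateIdError, match="Liver structure"):
            ont.add_concept(concept("b", fsn="Liver structure (body structure)"))


class TestAxioms:
    def setup_method(self):
        self.ont = Ontology()
        for cid in ("liver-e", "abd-e"):
            self.ont.add_concept(concept(cid))
        self.ont.add_role(Role("constitutional-part-of", "Constitutional part of"))

    def test_part_axiom_accepted(self):
        ax = subclass_of("liver-e", some("constitutional-part-of", "abd-e"))
        self.ont.add_axiom(ax)
        assert ax in self.ont.axioms

    def test_undeclared_concept_rejected_naming_it(self):
        with pytest.raises(UnknownIdError, match="'X'"):
            self.ont.add_axiom(subclass_of("liver-e", "X"))

    def test_undeclared_role_rejected(self):
        with pytest.raises(UnknownIdError, match="part-of-nowhere"):
            self.ont.add_axiom(
                subclass_of("liver-e", some("part-of-nowhere", "abd-e"))
            )

    def test_adding_same_axiom_twice_is_idempotent(self):
        ax = subclass_of("liver-e", some("constitutional-part-of", "abd-e"))
        self.ont.add_axiom(ax).add_axiom(ax)
        assert self.ont.axioms.count(ax) == 1

    def test_second_equivalence_for_same_name_rejected(self):
        self.ont.add_axiom(equivalent("liver-e", some("constitutional-part-of", "abd-e")))
        with pytest.raises(OntologyError, match="liver-e"):
            self.ont.add_axiom(equivalent("liver-e", Named("abd-e")))

    def test_equivalent_axiom_requires_named_left(self):
        with pytest.raises(ValueError):
            Axiom(AxiomKind.EQUIVALENT,
                  some("constitutional-part-of", "abd-e"), Named("liver-e"))

    def test_remove_axiom_requires_stated_axiom(self):
        with pytest.raises(OntologyError):
            self.ont.remove_axiom(subclass_of("liver-e", "abd-e"))


class TestStructuralEquality:
    def test_conjunction_is_commutative_and_associative(self):
        a, b, c = Named("a"), Named("b"), Named("c")
        assert conj(a, b) == conj(b, a)
        assert conj(conj(a, b), c) == conj(a, conj(b, c)) == conj(a, b, c)

    def test_conjunction_is_idempotent(self):
        a, b = Named("a"), Named("b")
        assert conj(a, a, b) == conj(a, b)
        assert conj(a, a) == a

    def test_empty_conjunction_rejected(self):
        with pytest.raises(ValueError):
            Conjunction(frozenset())

    def test_existential_equality_is_structural(self):
        assert some("r", conj(Named("a"), Named("b"))) == Existential(
            "r", Conjunction(frozenset({Named("b"), Named("a")}))
        )

    @given(st.permutations(["a", "b", "c", "d"]))
    def test_canonical_form_is_order_insensitive(self, order):
        expr = conj(*(Named(x) for x in order))
        assert canonical(expr) == canonical(conj(*(Named(x) for x in "abcd")))


@given(st.permutations(list(range(6))))
def test_assembly_is_order_independent(order):
    """Any permutation of the same declarations yields an equal ontology."""
    role = Role("p", "part of", transitive=True)
    concepts = [concept(f"c{i}") for i in range(4)]
    axioms = [
        subclass_of("c0", "c1"),
        subclass_of("c1", some("p", "c2")),
    ]
    steps = concepts + axioms

    def build(sequence):
        ont = Ontology().add_role(role)
        pending = list(sequence)
        while pending:  # axioms may precede their concepts in the permutation
            progressed = False
            for step in list(pending):
                try:
                    if isinstance(step, ConceptRef):
                        ont.add_concept(step)
                    else:
                        ont.add_axiom(step)
                except UnknownIdError:
                    continue
                pending.remove(step)
                progressed = True
            assert progressed
        return ont

    reference = build(steps)
    shuffled = build([steps[i] for i in order])
    assert reference == shuffled
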