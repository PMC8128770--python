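"""SEP triplet, cavity/content and dependent-definition patterns."""

import pytest

from seponto.core_model import Named, Ontology, OntologyError, UnknownIdError
from seponto.el_reasoner import classify
from seponto.sep_builder import (
    ALL_OR_PART_OF,
    PROPER_PART_OF,
    add_meronymy_roles,
    assert_part,
    define_dependent,
    make_cavity_wall_content,
    make_sep_triplet,
)


@pytest.fixture
def ont():
    return add_meronymy_roles(Ontology())


class TestSEPTriplet:
    def test_triplet_emits_exactly_the_four_defining_axioms(self, ont):
        t = make_sep_triplet(ont, "liver")
        assert len(t.axioms) == 4
        kinds = sorted(ax.kind.value for ax in t.axioms)
        assert kinds == ["equivalent", "equivalent", "subclass_of", "subclass_of"]
        assert set(ont.axioms) == set(t.axioms)
        # the structure definition uses all-or-part-of, the part proper-part-of
        defs = {ax.left: ax.right for ax in t.axioms if ax.kind.value == "equivalent"}
        assert defs[Named(t.structure)].role == ALL_OR_PART_OF
        assert defs[Named(t.part)].role == PROPER_PART_OF

    def test_entire_and_part_classified_under_structure(self, ont):
        t = make_sep_triplet(ont, "liver")
        tax = classify(ont)
        assert tax.contains(t.entire, t.structure)
        assert tax.contains(t.part, t.structure)
        assert not tax.contains(t.entire, t.part)
        assert not tax.contains(t.part, t.entire)

    def test_part_concept_without_declared_parts_has_no_subclasses(self, ont):
        t = make_sep_triplet(ont, "liver")
        assert classify(ont).descendants(t.part) == []

    def test_independent_triplets_do_not_cross_subsume(self, ont):
        t1 = make_sep_triplet(ont, "liver")
        t2 = make_sep_triplet(ont, "lung")
        tax = classify(ont)
        for a in (t1.entire, t1.part, t1.structure):
            for b in (t2.entire, t2.part, t2.structure):
                assert not tax.contains(a, b)
                assert not tax.contains(b, a)

    def test_id_collision_rejected(self, ont):
        make_sep_triplet(ont, "liver")
        with pytest.raises(OntologyError):
            make_sep_triplet(ont, "liver")

    def test_empty_label_rejected(self, ont):
        with pytest.raises(OntologyError):
            make_sep_triplet(ont, "")


class TestAssertPart:
    def test_regional_part_classifies_structure_under_parent(self, ont):
        liver = make_sep_triplet(ont, "liver")
        lobe = make_sep_triplet(ont, "lobe of liver")
        assert_part(ont, lobe.entire, liver.entire, "regional")
        tax = classify(ont)
        assert tax.contains(lobe.structure, liver.part)
        assert tax.contains(lobe.structure, liver.structure)

    def test_two_step_part_chain_propagates_to_grandparent(self, ont):
        # lobe -> liver -> abdomen proper: two applications of the
        # all-or-part-of composition, checkable by hand
        liver = make_sep_triplet(ont, "liver")
        lobe = make_sep_triplet(ont, "lobe of liver")
        abd = make_sep_triplet(ont, "abdomen proper")
        assert_part(ont, lobe.entire, liver.entire, "regional")
        assert_part(ont, liver.entire, abd.entire, "constitutional")
        tax = classify(ont)
        assert tax.contains(lobe.structure, abd.structure)
        assert tax.contains(lobe.structure, abd.part)
        # propagation also holds within the part hierarchy (proper-part-of
        # is itself transitive)
        assert tax.contains(lobe.part, abd.part)

    def test_mixed_kind_chain_propagates(self, ont):
        a = make_sep_triplet(ont, "a")
        b = make_sep_triplet(ont, "b")
        c = make_sep_triplet(ont, "c")
        assert_part(ont, a.entire, b.entire, "systemic")
        assert_part(ont, b.entire, c.entire, "regional")
        assert classify(ont).contains(a.structure, c.structure)

    def test_self_part_terminates_without_new_subsumptions(self, ont):
        liver = make_sep_triplet(ont, "liver")
        lung = make_sep_triplet(ont, "lung")
        before = classify(ont).closure
        assert_part(ont, liver.entire, liver.entire, "regional")
        after = classify(ont).closure
        # degenerate self-part adds entire ⊑ own part but nothing across
        # distinct entities
        new = after - before
        assert all(a.startswith("X-liver") and b.startswith("X-liver")
                   for a, b in new)
        assert not classify(ont).contains(liver.structure, lung.structure)

    def test_unknown_ids_and_kinds_rejected(self, ont):
        liver = make_sep_triplet(ont, "liver")
        with pytest.raises(UnknownIdError):
            assert_part(ont, "nope", liver.entire, "regional")
        with pytest.raises(OntologyError, match="lateral"):
            assert_part(ont, liver.entire, liver.entire, "lateral")


class TestCavityContentIntra:
    def test_cavity_and_content_subsumed_by_intra(self, ont):
        cavity, content, intra, _ = make_cavity_wall_content(ont, "abdominopelvic")
        tax = classify(ont)
        assert tax.contains(cavity, intra)
        assert tax.contains(content, intra)
        assert ont.concept(intra).fsn.startswith("Intra-abdominopelvic")

    def test_wall_not_subsumed_by_intra(self, ont):
        # "intra" = space and contents; the walls delineate but are excluded
        cavity, content, intra, _ = make_cavity_wall_content(ont, "abdominopelvic")
        wall = make_sep_triplet(ont, "anterior abdominal wall")
        tax = classify(ont)
        assert not tax.contains(wall.structure, intra)
        assert not tax.contains(wall.entire, intra)

    def test_empty_label_rejected(self, ont):
        with pytest.raises(OntologyError):
            make_cavity_wall_content(ont, "")


class TestDefineDependent:
    def test_dependents_follow_site_hierarchy(self, ont):
        liver = make_sep_triplet(ont, "liver")
        abd = make_sep_triplet(ont, "abdomen proper")
        assert_part(ont, liver.entire, abd.entire, "constitutional")
        d_liver = define_dependent(ont, "Disorder of liver", liver.structure)
        d_abd = define_dependent(ont, "Disorder of abdomen proper", abd.structure)
        assert classify(ont).contains(d_liver, d_abd)

    def test_unrelated_sites_give_unrelated_dependents(self, ont):
        liver = make_sep_triplet(ont, "liver")
        lung = make_sep_triplet(ont, "lung")
        d1 = define_dependent(ont, "Disorder of liver", liver.structure)
        d2 = define_dependent(ont, "Disorder of lung", lung.structure)
        tax = classify(ont)
        assert not tax.contains(d1, d2) and not tax.contains(d2, d1)

    def test_same_site_dependents_are_mutually_equivalent(self, ont):
        liver = make_sep_triplet(ont, "liver")
        d1 = define_dependent(ont, "Hepatopathy", liver.structure)
        d2 = define_dependent(ont, "Disorder of liver", liver.structure)
        tax = classify(ont)
        assert tax.contains(d1, d2) and tax.contains(d2, d1)
        assert any(d1 in group and d2 in group
                   for group in tax.equivalence_classes)

    def test_procedure_kind_uses_procedure_site(self, ont):
        liver = make_sep_triplet(ont, "liver")
        pid = define_dependent(ont, "Biopsy of liver", liver.structure, "procedure")
        ax = ont.equivalence_definition(pid)
        roles = {op.role for op in ax.right.operands
                 if hasattr(op, "role")}
        assert roles == {"procedure-site"}

    def test_unknown_site_and_kind_rejected(self, ont):
        liver = make_sep_triplet(ont, "liver")
        with pytest.raises(UnknownIdError):
            define_dependent(ont, "Disorder of nothing", "nope")
        with pytest.raises(OntologyError, match="finding"):
            define_dependent(ont, "x", liver.structure, "finding")
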