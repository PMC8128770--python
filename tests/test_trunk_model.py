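"""The trunk anatomy fixture: identifiers, suites, SEP and containment laws."""

import networkx as nx
import pytest

from seponto.el_reasoner import classify
from seponto.trunk_model import (
    ABDOMEN_PROPER_CAVITY,
    ABDOMEN_PROPER_REGION,
    ABDOMEN_PROPER_SEGMENT_S,
    ABDOMEN_REGION,
    ABDOMINAL_XS_S,
    ABDOMINOPELVIC_CAVITY,
    ALLOCATED_PREFERRED_SYNONYMS,
    INTRA_TRUE_PELVIS,
    PELVIC_REGION,
    PELVIC_SEGMENT_S,
    PELVIC_XS_S,
    POSTERIOR_WALL_ABDOMEN_PROPER_S,
    SHARED_TRUE_PELVIS_CONTENTS,
    THORACIC_CAVITY,
    THORACIC_SEGMENT_S,
    THORACIC_XS_S,
    TRUE_PELVIS_CAVITY,
    TRUNK_S,
    asserted_placement_graph,
    build_trunk_model,
    negative_suite,
    positive_suite,
)

# released identifier -> fully specified name, exactly as published
RELEASED_FSNS = {
    TRUNK_S: "Trunk structure (body structure)",
    THORACIC_CAVITY: "Thoracic cavity structure (body structure)",
    ABDOMINOPELVIC_CAVITY: "Structure of abdominopelvic cavity (body structure)",
    ABDOMEN_PROPER_CAVITY:
        "Structure of abdominopelvic cavity excluding true pelvic cavity "
        "(body structure)",
    TRUE_PELVIS_CAVITY: "Structure of cavity of true pelvis (body structure)",
    THORACIC_SEGMENT_S:
        "Structure of thoracic segment of trunk (body structure)",
    ABDOMEN_PROPER_SEGMENT_S:
        "Structure of abdominopelvic segment excluding true pelvic segment "
        "of trunk (body structure)",
    PELVIC_SEGMENT_S: "Structure of pelvic segment of trunk (body structure)",
    THORACIC_XS_S:
        "Structure of thoracic cross-sectional segment of trunk "
        "(body structure)",
    ABDOMINAL_XS_S:
        "Structure of abdominal cross-sectional segment of trunk "
        "(body structure)",
    PELVIC_XS_S:
        "Structure of pelvic cross-sectional segment of trunk "
        "(body structure)",
    ABDOMEN_REGION:
        "Structure of abdominopelvic cavity and/or content of abdominopelvic "
        "cavity and/or anterior abdominal wall (body structure)",
    ABDOMEN_PROPER_REGION:
        "Structure of abdominopelvic cavity and/or intra-abdominopelvic "
        "content and/or anterior abdominal wall excluding intra-pelvic "
        "structure of true pelvis (body structure)",
    PELVIC_REGION: "Structure of pelvis (body structure)",
    POSTERIOR_WALL_ABDOMEN_PROPER_S:
        "Posterior wall of abdomen proper (body structure)",
}


class TestIdentifiers:
    def test_released_sctids_resolve_with_published_fsns(self, trunk):
        for sctid, fsn in RELEASED_FSNS.items():
            assert trunk.ontology.concept(sctid).fsn == fsn

    def test_local_ids_use_reserved_namespace(self, trunk):
        for cid in trunk.ontology.concepts:
            assert cid in RELEASED_FSNS or cid.startswith("X-"), cid

    def test_each_allocated_synonym_names_exactly_one_concept(self, trunk):
        for term, expected_id in ALLOCATED_PREFERRED_SYNONYMS.items():
            holders = [
                c.id for c in trunk.ontology.concepts.values()
                if c.preferred_term == term
            ]
            assert holders == [expected_id]


class TestCuratedSuites:
    def test_suites_are_nonempty_disjoint_and_cited(self):
        pos, neg = positive_suite(), negative_suite()
        assert len(pos) >= 15 and len(neg) >= 8
        pos_pairs = {(e.sub, e.super) for e in pos}
        neg_pairs = {(e.sub, e.super) for e in neg}
        assert not pos_pairs & neg_pairs
        assert all(e.source for e in pos + neg)
        assert all(e.expected for e in pos)
        assert not any(e.expected for e in neg)

    def test_every_positive_entailment_holds(self, trunk_taxonomy):
        failures = [
            (e.sub, e.super, e.source)
            for e in positive_suite()
            if not trunk_taxonomy.contains(e.sub, e.super)
        ]
        assert failures == []

    def test_every_negative_entailment_fails(self, trunk_taxonomy):
        violations = [
            (e.sub, e.super, e.source)
            for e in negative_suite()
            if trunk_taxonomy.contains(e.sub, e.super)
        ]
        assert violations == []


class TestSEPInvariants:
    def test_every_triplet_obeys_the_sep_laws(self, trunk, trunk_taxonomy):
        for label, t in trunk.triplets.items():
            assert trunk_taxonomy.contains(t.entire, t.structure), label
            assert trunk_taxonomy.contains(t.part, t.structure), label
            assert not trunk_taxonomy.contains(t.entire, t.part), label
            assert not trunk_taxonomy.contains(t.part, t.entire), label


class TestGenderSymmetry:
    @pytest.mark.parametrize("male,female", [
        (True, True), (True, False), (False, True), (False, False),
    ])
    def test_shared_contents_placement_independent_of_gender_load(
        self, male, female
    ):
        model = build_trunk_model(include_male=male, include_female=female)
        tax = classify(model.ontology)
        for label in SHARED_TRUE_PELVIS_CONTENTS:
            s = model.triplets[label].structure
            assert tax.contains(s, INTRA_TRUE_PELVIS), label
            assert tax.contains(s, PELVIC_REGION), label


class TestContainmentLaw:
    def test_structure_subsumption_requires_an_asserted_placement_path(
        self, trunk, trunk_taxonomy
    ):
        """A structure sits under another structure only when the asserted
        placement graph (part axioms plus named subclass placements) provides
        a path — i.e. only entities entirely within the boundary."""
        g = asserted_placement_graph(trunk)
        reach = {n: nx.descendants(g, n) | {n} for n in g.nodes}
        structures = {t.structure for t in trunk.triplets.values()}
        for s1 in structures:
            for s2 in structures:
                if s1 == s2:
                    continue
                classified = trunk_taxonomy.contains(s1, s2)
                asserted = s2 in reach[s1]
                assert classified == asserted, (s1, s2)


def test_trunk_classification_terminates_with_abdomen_concept(trunk, trunk_taxonomy):
    c = trunk.ontology.concept(ABDOMEN_REGION)
    assert c.preferred_term == "Abdomen"
    assert trunk_taxonomy.contains(ABDOMEN_REGION, ABDOMEN_REGION)
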