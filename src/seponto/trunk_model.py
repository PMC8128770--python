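"""Executable regional anatomy of the human trunk.

This module transcribes the published SNOMED CT model of the trunk's
regional volumes into an EL ontology: the cavities (thoracic,
abdominopelvic, abdomen proper, true and false pelvis), the three regional
segments and the radiological cross-sectional segments, the walls and
diaphragms, the three complex clinical-region variants of "abdomen", and a
set of exemplar contents and dependent disorders/procedures sufficient to
exercise every part-whole inference the model is meant to support.

Identifier policy: released SNOMED CT identifiers (SCTIDs) are used verbatim
where they exist; every other concept lives in the reserved local ``X-``
namespace so fixture ids can never collide with SCTIDs.

The curated positive/negative entailment suites record, with a citation
string per entry, which subsumptions the model must produce and which it
must *not* produce (the containment law: a structure is subsumed by another
structure only if it lies entirely within the latter's boundary).
"""

from __future__ import annotations

from dataclasses import dataclass

from .core_model import ConceptRef, Named, Ontology, SemanticClass, some, subclass_of
from .sep_builder import (
    REGIONAL_PART_OF,
    SEPTriplet,
    add_meronymy_roles,
    assert_part,
    define_dependent,
    make_cavity_wall_content,
    make_sep_triplet,
)

# --- released identifiers (SCTIDs) -----------------------------------------

TRUNK_S = "22943007"
THORACIC_CAVITY = "43799004"
ABDOMINOPELVIC_CAVITY = "818987002"
ABDOMEN_PROPER_CAVITY = "281902004"
TRUE_PELVIS_CAVITY = "816991004"
THORACIC_SEGMENT_S = "67734004"
ABDOMEN_PROPER_SEGMENT_S = "818985005"
PELVIC_SEGMENT_S = "609617007"
THORACIC_XS_S = "816094009"
ABDOMINAL_XS_S = "818981001"
PELVIC_XS_S = "816092008"
ABDOMEN_REGION = "818983003"
ABDOMEN_PROPER_REGION = "818984009"
PELVIC_REGION = "12921003"
POSTERIOR_WALL_ABDOMEN_PROPER_S = "827003001"

# --- local ids used across suites and scenarios ----------------------------

FALSE_PELVIS_CAVITY = "X-false-pelvis-cavity"
FALSE_OR_TRUE_PELVIS_CAVITY = "X-false-or-true-pelvis-cavity"
ABDOMINOPELVIC_SEGMENT_S = "X-abdominopelvic-segment-s"
ABDOMINOPELVIC_XS_S = "X-abdominopelvic-cross-section-s"
INTRA_THORACIC = "X-intra-thoracic"
INTRA_ABDOMINOPELVIC = "X-intra-abdominopelvic"
INTRA_ABDOMINAL_PROPER = "X-intra-abdominal-proper"
INTRA_TRUE_PELVIS = "X-intra-true-pelvis"
CONTENT_THORACIC = "X-thoracic-content"
CONTENT_ABDOMINOPELVIC = "X-abdominopelvic-content"
CONTENT_ABDOMINAL_PROPER = "X-abdominal-proper-content"
CONTENT_TRUE_PELVIS = "X-true-pelvis-content"
CONTENT_FALSE_PELVIS = "X-false-pelvis-content"

#: The three clinical "abdomen" variants and their allocated preferred
#: synonyms (the single-synonym policy: each term names exactly one concept).
ALLOCATED_PREFERRED_SYNONYMS = {
    "Abdomen": ABDOMEN_REGION,
    "Abdomen proper": ABDOMEN_PROPER_REGION,
    "Cross-sectional abdomen": ABDOMINAL_XS_S,
}

#: Contents of the true pelvis shared by both sexes.
SHARED_TRUE_PELVIS_CONTENTS = (
    "urinary bladder",
    "retropubic space",
    "presacral space",
    "sigmoid colon",
    "rectum",
    "pelvic portion of ureter",
)
MALE_TRUE_PELVIS_CONTENTS = ("puboprostatic ligament", "prostate", "seminal vesicle")
FEMALE_TRUE_PELVIS_CONTENTS = ("uterus", "ovary", "fallopian tube")


@dataclass(frozen=True)
class CuratedEntailment:
    """One published subsumption claim: expected True (holds) or False."""

    sub: str
    super: str
    expected: bool
    source: str


@dataclass
class TrunkModel:
    """The assembled fixture: ontology plus its SEP triplet registry."""

    ontology: Ontology
    triplets: dict  # label -> SEPTriplet


def structure_of(model: TrunkModel, label: str) -> str:
    return model.triplets[label].structure


def entire_of(model: TrunkModel, label: str) -> str:
    return model.triplets[label].entire


def build_trunk_model(
    *, include_male: bool = True, include_female: bool = True
) -> TrunkModel:
    """Build the trunk fixture; gender-specific contents can be toggled.

    Both gendered content sets are loaded by default (they are ordinary
    content concepts; no sex axioms are stated, and the model asserts
    nothing that depends on which set is present).
    """
    ont = Ontology()
    add_meronymy_roles(ont)
    triplets: dict = {}

    def sep(label, ids=None, **kw) -> SEPTriplet:
        t = make_sep_triplet(ont, label, ids, **kw)
        triplets[label] = t
        return t

    def sctid_sep(label, structure_id, structure_fsn, structure_preferred=None, **kw):
        slug = label.lower().replace(" ", "-").replace("/", "-")
        cap = label[0].upper() + label[1:]
        t = make_sep_triplet(
            ont,
            label,
            (f"X-{slug}-e", f"X-{slug}-p", structure_id),
            names=(f"Entire {label}", f"{cap} part", structure_fsn),
            structure_preferred=structure_preferred or structure_fsn,
            **kw,
        )
        triplets[label] = t
        return t

    # -- trunk and regional segments (SEP entities) ---------------------
    trunk = sctid_sep("trunk", TRUNK_S, "Trunk structure", "Trunk structure")
    thor_seg = sctid_sep(
        "thoracic segment of trunk",
        THORACIC_SEGMENT_S,
        "Structure of thoracic segment of trunk",
        "Thoracic segment of trunk",
        structure_class=SemanticClass.SEGMENT,
    )
    ap_seg = sep(
        "abdominopelvic segment of trunk",
        ("X-abdominopelvic-segment-e", "X-abdominopelvic-segment-p", ABDOMINOPELVIC_SEGMENT_S),
        names=(
            "Entire abdominopelvic segment of trunk",
            "Abdominopelvic segment of trunk part",
            "Structure of abdominopelvic segment of trunk",
        ),
        structure_class=SemanticClass.SEGMENT,
    )
    app_seg = sctid_sep(
        "abdomen proper segment of trunk",
        ABDOMEN_PROPER_SEGMENT_S,
        "Structure of abdominopelvic segment excluding true pelvic segment of trunk",
        "Abdomen proper segment of trunk",
        structure_class=SemanticClass.SEGMENT,
    )
    pelv_seg = sctid_sep(
        "pelvic segment of trunk",
        PELVIC_SEGMENT_S,
        "Structure of pelvic segment of trunk",
        "Structure of pelvic segment of trunk",
        structure_class=SemanticClass.SEGMENT,
    )
    assert_part(ont, thor_seg.entire, trunk.entire, "regional")
    assert_part(ont, ap_seg.entire, trunk.entire, "regional")
    assert_part(ont, app_seg.entire, ap_seg.entire, "regional")
    assert_part(ont, pelv_seg.entire, ap_seg.entire, "regional")

    # -- cross-sectional (radiological) segments ------------------------
    thor_xs = sctid_sep(
        "thoracic cross-sectional segment of trunk",
        THORACIC_XS_S,
        "Structure of thoracic cross-sectional segment of trunk",
        "Cross-sectional thorax",
        structure_class=SemanticClass.CROSS_SECTION,
    )
    abd_xs = sctid_sep(
        "abdominal cross-sectional segment of trunk",
        ABDOMINAL_XS_S,
        "Structure of abdominal cross-sectional segment of trunk",
        "Cross-sectional abdomen",
        structure_class=SemanticClass.CROSS_SECTION,
    )
    pelv_xs = sctid_sep(
        "pelvic cross-sectional segment of trunk",
        PELVIC_XS_S,
        "Structure of pelvic cross-sectional segment of trunk",
        "Cross-sectional pelvis",
        structure_class=SemanticClass.CROSS_SECTION,
    )
    ap_xs = sep(
        "abdominopelvic cross-sectional segment of trunk",
        ("X-abdominopelvic-cross-section-e", "X-abdominopelvic-cross-section-p", ABDOMINOPELVIC_XS_S),
        names=(
            "Entire abdominopelvic cross-sectional segment of trunk",
            "Abdominopelvic cross-sectional segment of trunk part",
            "Structure of abdominopelvic cross-sectional segment of trunk",
        ),
        structure_class=SemanticClass.CROSS_SECTION,
    )
    # shared T9-T12 band: the thoracic and abdominal cross-sections overlap
    band = sep(
        "T9-T12 cross-sectional band of trunk",
        structure_class=SemanticClass.CROSS_SECTION,
    )
    assert_part(ont, thor_xs.entire, trunk.entire, "regional")
    assert_part(ont, ap_xs.entire, trunk.entire, "regional")
    assert_part(ont, abd_xs.entire, ap_xs.entire, "regional")
    assert_part(ont, pelv_xs.entire, ap_xs.entire, "regional")
    assert_part(ont, band.entire, thor_xs.entire, "regional")
    assert_part(ont, band.entire, abd_xs.entire, "regional")

    # -- cavities, contents and intra- aggregations ---------------------
    make_cavity_wall_content(
        ont,
        "thoracic",
        ids=(THORACIC_CAVITY, CONTENT_THORACIC, INTRA_THORACIC),
        cavity_fsn="Thoracic cavity structure",
        cavity_preferred="Thoracic cavity",
        intra_fsn="Intra-thoracic structure",
    )
    make_cavity_wall_content(
        ont,
        "abdominopelvic",
        ids=(ABDOMINOPELVIC_CAVITY, CONTENT_ABDOMINOPELVIC, INTRA_ABDOMINOPELVIC),
        cavity_fsn="Structure of abdominopelvic cavity",
        cavity_preferred="Abdominopelvic cavity",
        intra_fsn="Intra-abdominopelvic structure",
    )
    make_cavity_wall_content(
        ont,
        "abdominal proper",
        ids=(ABDOMEN_PROPER_CAVITY, CONTENT_ABDOMINAL_PROPER, INTRA_ABDOMINAL_PROPER),
        cavity_fsn="Structure of abdominopelvic cavity excluding true pelvic cavity",
        cavity_preferred="Abdomen proper cavity",
        intra_fsn="Intra-abdominal proper structure",
    )
    make_cavity_wall_content(
        ont,
        "true pelvis",
        ids=(TRUE_PELVIS_CAVITY, CONTENT_TRUE_PELVIS, INTRA_TRUE_PELVIS),
        cavity_fsn="Structure of cavity of true pelvis",
        cavity_preferred="Cavity of true pelvis",
        intra_fsn="Intra-pelvic structure of true pelvis",
    )
    ont.add_concept(ConceptRef(
        id=FALSE_PELVIS_CAVITY,
        fsn="Structure of cavity of false pelvis (body structure)",
        preferred_term="Cavity of false pelvis",
        semantic_class=SemanticClass.CAVITY,
    ))
    ont.add_concept(ConceptRef(
        id=CONTENT_FALSE_PELVIS,
        fsn="Content of false pelvis cavity (body structure)",
        preferred_term="Content of false pelvis cavity",
        semantic_class=SemanticClass.CONTENT,
    ))
    # and/or aggregation: EL has no disjunction, so the combined pelvic
    # cavity is primitive with each disjunct asserted into it
    ont.add_concept(ConceptRef(
        id=FALSE_OR_TRUE_PELVIS_CAVITY,
        fsn="Structure of cavity of false and/or true pelvis (body structure)",
        preferred_term="Cavity of false and/or true pelvis",
        semantic_class=SemanticClass.CAVITY,
    ))
    ont.add_axioms([
        # cavity nesting (a cavity volume lies entirely within the larger one)
        subclass_of(ABDOMEN_PROPER_CAVITY, ABDOMINOPELVIC_CAVITY),
        subclass_of(TRUE_PELVIS_CAVITY, ABDOMINOPELVIC_CAVITY),
        subclass_of(FALSE_PELVIS_CAVITY, ABDOMEN_PROPER_CAVITY),
        subclass_of(FALSE_PELVIS_CAVITY, FALSE_OR_TRUE_PELVIS_CAVITY),
        subclass_of(TRUE_PELVIS_CAVITY, FALSE_OR_TRUE_PELVIS_CAVITY),
        subclass_of(FALSE_OR_TRUE_PELVIS_CAVITY, ABDOMINOPELVIC_CAVITY),
        # content nesting mirrors the cavity nesting
        subclass_of(CONTENT_ABDOMINAL_PROPER, CONTENT_ABDOMINOPELVIC),
        subclass_of(CONTENT_TRUE_PELVIS, CONTENT_ABDOMINOPELVIC),
        subclass_of(CONTENT_FALSE_PELVIS, CONTENT_ABDOMINAL_PROPER),
        # intra- nesting
        subclass_of(INTRA_ABDOMINAL_PROPER, INTRA_ABDOMINOPELVIC),
        subclass_of(INTRA_TRUE_PELVIS, INTRA_ABDOMINOPELVIC),
        # a cavity with its contents lies within its segment volume
        subclass_of(INTRA_THORACIC, thor_seg.structure),
        subclass_of(INTRA_ABDOMINOPELVIC, ap_seg.structure),
        subclass_of(INTRA_ABDOMINAL_PROPER, app_seg.structure),
        subclass_of(INTRA_TRUE_PELVIS, pelv_seg.structure),
        # the false pelvis volume belongs to BOTH the abdomen proper segment
        # (via its cavity nesting) and the pelvic segment: not disjoint
        subclass_of(FALSE_PELVIS_CAVITY, pelv_seg.structure),
    ])

    # -- walls and diaphragms -------------------------------------------
    chest_wall = sep("chest wall", structure_class=SemanticClass.WALL)
    ap_wall = sep(
        "wall of abdominopelvic segment of trunk",
        structure_class=SemanticClass.WALL,
    )
    app_wall = sep(
        "wall of abdominal proper segment of trunk",
        structure_class=SemanticClass.WALL,
    )
    ant_wall = sep("anterior abdominal wall", structure_class=SemanticClass.WALL)
    post_wall = sctid_sep(
        "posterior wall of abdomen proper",
        POSTERIOR_WALL_ABDOMEN_PROPER_S,
        "Posterior wall of abdomen proper",
        "Posterior wall of abdomen proper",
        structure_class=SemanticClass.WALL,
    )
    pelv_wall = sep("pelvic wall", structure_class=SemanticClass.WALL)
    thor_diaphragm = sep("thoracic diaphragm", structure_class=SemanticClass.WALL)
    pelv_diaphragm = sep("pelvic diaphragm", structure_class=SemanticClass.WALL)
    lumbar = sep("lumbar vertebral column")
    perineum = sep("perineum")
    genitalia = sep("external genitalia")

    assert_part(ont, chest_wall.entire, thor_seg.entire, "constitutional")
    assert_part(ont, ap_wall.entire, ap_seg.entire, "constitutional")
    assert_part(ont, app_wall.entire, ap_wall.entire, "regional")
    assert_part(ont, app_wall.entire, app_seg.entire, "constitutional")
    assert_part(ont, ant_wall.entire, app_wall.entire, "regional")
    assert_part(ont, post_wall.entire, app_wall.entire, "regional")
    assert_part(ont, pelv_wall.entire, ap_wall.entire, "regional")
    assert_part(ont, pelv_wall.entire, pelv_seg.entire, "constitutional")
    assert_part(ont, thor_diaphragm.entire, ap_seg.entire, "constitutional")
    assert_part(ont, pelv_diaphragm.entire, pelv_seg.entire, "constitutional")
    assert_part(ont, lumbar.entire, post_wall.entire, "constitutional")
    # the perineum and external genitalia belong to the pelvic segment but
    # NOT to the pelvic region (which is bounded by the pelvic diaphragm)
    assert_part(ont, perineum.entire, pelv_seg.entire, "constitutional")
    assert_part(ont, genitalia.entire, pelv_seg.entire, "constitutional")

    # -- complex clinical regions (primitive and/or aggregations) -------
    ont.add_concept(ConceptRef(
        id=ABDOMEN_REGION,
        fsn=(
            "Structure of abdominopelvic cavity and/or content of "
            "abdominopelvic cavity and/or anterior abdominal wall (body structure)"
        ),
        preferred_term="Abdomen",
        semantic_class=SemanticClass.CLINICAL_REGION,
    ))
    ont.add_concept(ConceptRef(
        id=ABDOMEN_PROPER_REGION,
        fsn=(
            "Structure of abdominopelvic cavity and/or intra-abdominopelvic "
            "content and/or anterior abdominal wall excluding intra-pelvic "
            "structure of true pelvis (body structure)"
        ),
        preferred_term="Abdomen proper",
        semantic_class=SemanticClass.CLINICAL_REGION,
    ))
    ont.add_concept(ConceptRef(
        id=PELVIC_REGION,
        fsn="Structure of pelvis (body structure)",
        preferred_term="Pelvic region",
        semantic_class=SemanticClass.CLINICAL_REGION,
    ))
    ont.add_axioms([
        subclass_of(INTRA_ABDOMINOPELVIC, ABDOMEN_REGION),
        subclass_of(ant_wall.structure, ABDOMEN_REGION),
        subclass_of(ABDOMEN_REGION, ap_seg.structure),
        subclass_of(INTRA_ABDOMINAL_PROPER, ABDOMEN_PROPER_REGION),
        subclass_of(ant_wall.structure, ABDOMEN_PROPER_REGION),
        subclass_of(ABDOMEN_PROPER_REGION, ABDOMEN_REGION),
        subclass_of(ABDOMEN_PROPER_REGION, app_seg.structure),
        # pelvic region: wall, cavity and content of both pelves plus the
        # pelvic diaphragm; excludes perineum and external genitalia
        subclass_of(pelv_wall.structure, PELVIC_REGION),
        subclass_of(FALSE_OR_TRUE_PELVIS_CAVITY, PELVIC_REGION),
        subclass_of(INTRA_TRUE_PELVIS, PELVIC_REGION),
        subclass_of(pelv_diaphragm.structure, PELVIC_REGION),
        subclass_of(PELVIC_REGION, pelv_seg.structure),
        subclass_of(PELVIC_REGION, pelv_xs.structure),
    ])

    # -- exemplar contents ----------------------------------------------
    digestive = sep("digestive system")
    liver = sep("liver", names=("Entire liver", "Liver part", "Liver structure"))
    lobe = sep("lobe of liver")
    parenchyma = sep("parenchyma of liver")
    assert_part(ont, lobe.entire, liver.entire, "regional")
    assert_part(ont, parenchyma.entire, liver.entire, "constitutional")
    assert_part(ont, liver.entire, app_seg.entire, "constitutional")
    assert_part(ont, liver.entire, digestive.entire, "systemic")
    ont.add_axiom(subclass_of(liver.structure, CONTENT_ABDOMINAL_PROPER))

    large_int = sep("large intestine")
    descending = sep("descending colon")
    iliac = sep("iliac colon")
    sigmoid = sep("sigmoid colon")
    rectum = sep("rectum")
    anal = sep("anal canal")
    assert_part(ont, descending.entire, large_int.entire, "regional")
    assert_part(ont, iliac.entire, descending.entire, "regional")
    assert_part(ont, sigmoid.entire, large_int.entire, "regional")
    assert_part(ont, rectum.entire, large_int.entire, "regional")
    assert_part(ont, anal.entire, large_int.entire, "regional")
    # the anal canal lies below the pelvic diaphragm, in the perineum; the
    # large intestine therefore is NOT entirely intra-abdominopelvic
    assert_part(ont, anal.entire, perineum.entire, "constitutional")
    assert_part(ont, large_int.entire, ap_seg.entire, "constitutional")
    assert_part(ont, large_int.entire, digestive.entire, "systemic")
    ont.add_axiom(subclass_of(descending.structure, CONTENT_ABDOMINAL_PROPER))
    # the iliac colon (distal descending colon in the false pelvis) is
    # clinically regarded as pelvic; this single axiom carries that placement
    assert_part(ont, iliac.entire, pelv_seg.entire, "regional")
    ont.add_axiom(subclass_of(iliac.structure, CONTENT_FALSE_PELVIS))

    aorta = sep("aorta")
    arch = sep("arch of aorta")
    abd_aorta = sep("abdominal aorta")
    assert_part(ont, arch.entire, aorta.entire, "regional")
    assert_part(ont, abd_aorta.entire, aorta.entire, "regional")
    assert_part(ont, aorta.entire, trunk.entire, "constitutional")
    ont.add_axiom(subclass_of(arch.structure, CONTENT_THORACIC))
    ont.add_axiom(subclass_of(abd_aorta.structure, CONTENT_ABDOMINAL_PROPER))

    ureter = sep("ureter")
    content_labels = list(SHARED_TRUE_PELVIS_CONTENTS)
    if include_male:
        content_labels += list(MALE_TRUE_PELVIS_CONTENTS)
    if include_female:
        content_labels += list(FEMALE_TRUE_PELVIS_CONTENTS)
    for label in content_labels:
        t = triplets.get(label) or sep(label)
        ont.add_axiom(subclass_of(t.structure, CONTENT_TRUE_PELVIS))
    if "pelvic portion of ureter" in triplets:
        assert_part(ont, triplets["pelvic portion of ureter"].entire,
                    ureter.entire, "regional")

    # -- dependent exemplars --------------------------------------------
    define_dependent(ont, "Disorder of liver", liver.structure, "disorder")
    define_dependent(
        ont, "Disorder of abdomen proper", app_seg.structure, "disorder",
        concept_id="X-disorder-of-abdomen-proper",
    )
    define_dependent(
        ont, "Disorder of abdominopelvic segment of trunk", ap_seg.structure,
        "disorder", concept_id="X-disorder-of-abdominopelvic-segment",
    )
    if "uterus" in triplets:
        define_dependent(
            ont, "Disorder of uterus", triplets["uterus"].structure, "disorder"
        )
    if "urinary bladder" in triplets:
        define_dependent(
            ont, "Disorder of urinary bladder",
            triplets["urinary bladder"].structure, "disorder",
        )
    define_dependent(ont, "CT of abdomen", abd_xs.structure, "procedure")
    define_dependent(ont, "CT of pelvis", pelv_xs.structure, "procedure")
    define_dependent(
        ont, "CT of abdomen and pelvis", ap_xs.structure, "procedure"
    )

    ont.set_primitive_flags()
    ont.validate()
    return TrunkModel(ontology=ont, triplets=triplets)


def build_trunk_ontology(
    *, include_male: bool = True, include_female: bool = True
) -> Ontology:
    """The trunk fixture ontology (see :func:`build_trunk_model`)."""
    return build_trunk_model(
        include_male=include_male, include_female=include_female
    ).ontology


def build_liver_exemplar() -> TrunkModel:
    """The small liver/partonomy exemplar used to illustrate SEP reasoning.

    Contains the liver, its lobe and parenchyma, the abdomen proper and
    abdominopelvic segment, and the digestive system, with the six classic
    SEP-style definitions (liver structure ≡ all-or-part-of some entire
    liver; lobe as regional part; parenchyma as constitutional part; liver
    as constitutional part of the abdomen proper and systemic part of the
    digestive system).  Small enough for the naive oracle's default guard
    territory, and the seed of several worked examples.
    """
    ont = Ontology()
    add_meronymy_roles(ont)
    triplets: dict = {}

    def sep(label, **kw):
        t = make_sep_triplet(ont, label, **kw)
        triplets[label] = t
        return t

    liver = sep("liver", names=("Entire liver", "Liver part", "Liver structure"))
    lobe = sep("lobe of liver")
    abd_proper = sep("abdomen proper")
    ap_seg = sep("abdominopelvic segment of trunk")
    digestive = sep("digestive system")
    ont.add_concept(ConceptRef(
        id="X-entire-organ",
        fsn="Entire organ (body structure)",
        preferred_term="Entire organ",
        semantic_class=SemanticClass.ENTIRE,
    ))
    ont.add_concept(ConceptRef(
        id="X-parenchyma-of-liver-s",
        fsn="Structure of parenchyma of liver (body structure)",
        preferred_term="Structure of parenchyma of liver",
        semantic_class=SemanticClass.STRUCTURE,
    ))
    from .sep_builder import CONSTITUTIONAL_PART_OF

    ont.add_axiom(subclass_of(liver.entire, "X-entire-organ"))
    assert_part(ont, liver.entire, abd_proper.entire, "constitutional")
    assert_part(ont, liver.entire, digestive.entire, "systemic")
    assert_part(ont, lobe.entire, liver.entire, "regional")
    ont.add_axiom(subclass_of(
        "X-parenchyma-of-liver-s", some(CONSTITUTIONAL_PART_OF, liver.entire)
    ))
    assert_part(ont, abd_proper.entire, ap_seg.entire, "regional")
    ont.set_primitive_flags()
    ont.validate()
    return TrunkModel(ontology=ont, triplets=triplets)


# ---------------------------------------------------------------------------
# Curated entailment suites
# ---------------------------------------------------------------------------

def positive_suite() -> list:
    """Subsumptions the published model asserts; all must hold."""
    m = build_trunk_model()
    s = lambda label: structure_of(m, label)  # noqa: E731
    return [
        CuratedEntailment(
            TRUE_PELVIS_CAVITY, ABDOMINOPELVIC_CAVITY, True,
            "cavities of the trunk: the abdominopelvic cavity comprises the abdomen "
            "proper and true pelvic cavities",
        ),
        CuratedEntailment(
            ABDOMEN_PROPER_CAVITY, ABDOMINOPELVIC_CAVITY, True,
            "abdomen proper cavity definition: abdomen proper cavity is the abdominopelvic cavity "
            "excluding the true pelvic cavity",
        ),
        CuratedEntailment(
            FALSE_PELVIS_CAVITY, ABDOMEN_PROPER_SEGMENT_S, True,
            "segment definitions: the abdomen proper segment includes the volume of the "
            "false pelvis",
        ),
        CuratedEntailment(
            FALSE_PELVIS_CAVITY, PELVIC_SEGMENT_S, True,
            "segment definitions: the pelvic segment also includes the false pelvis; the "
            "two segments are not disjoint",
        ),
        CuratedEntailment(
            FALSE_PELVIS_CAVITY, FALSE_OR_TRUE_PELVIS_CAVITY, True,
            "combined pelvic cavity definition: the combined pelvic cavity unites the false and true "
            "pelvic cavities",
        ),
        CuratedEntailment(
            s("urinary bladder"), INTRA_TRUE_PELVIS, True,
            "true-pelvis contents table: the urinary bladder lies within the "
            "cavity of the true pelvis",
        ),
        CuratedEntailment(
            s("sigmoid colon"), INTRA_TRUE_PELVIS, True,
            "true-pelvis contents table: sigmoid colon",
        ),
        CuratedEntailment(
            s("rectum"), INTRA_TRUE_PELVIS, True,
            "true-pelvis contents table: rectum",
        ),
        CuratedEntailment(
            s("prostate"), INTRA_TRUE_PELVIS, True,
            "true-pelvis contents table (male): prostate",
        ),
        CuratedEntailment(
            s("ovary"), PELVIC_REGION, True,
            "contents and pelvic-region definitions: true-pelvis contents fall within the pelvic region",
        ),
        CuratedEntailment(
            s("uterus"), ABDOMEN_REGION, True,
            "clinical 'Abdomen' definition: the clinical 'Abdomen' contains the uterus (native "
            "and gravid state)",
        ),
        CuratedEntailment(
            s("liver"), ABDOMEN_PROPER_SEGMENT_S, True,
            "meronymic-reasoning exemplar: the liver structure is part of the abdominal proper "
            "structure",
        ),
        CuratedEntailment(
            s("liver"), ABDOMINOPELVIC_SEGMENT_S, True,
            "meronymic-reasoning exemplar: the liver is also an abdominopelvic structure",
        ),
        CuratedEntailment(
            s("lobe of liver"), s("liver"), True,
            "meronymic-reasoning exemplar: Structure of lobe of liver is classified under Liver "
            "structure",
        ),
        CuratedEntailment(
            s("parenchyma of liver"), s("liver"), True,
            "meronymic-reasoning exemplar: parenchyma of liver is a constitutional part of the liver",
        ),
        CuratedEntailment(
            "X-disorder-of-liver", "X-disorder-of-abdomen-proper", True,
            "meronymic-reasoning exemplar: a disorder of liver is a disorder of the abdomen proper",
        ),
        CuratedEntailment(
            "X-disorder-of-liver", "X-disorder-of-abdominopelvic-segment", True,
            "meronymic-reasoning exemplar: ... and also a disorder of abdominopelvic segment of trunk",
        ),
        CuratedEntailment(
            s("arch of aorta"), INTRA_THORACIC, True,
            "meronymic-reasoning exemplar: the arch of the aorta lies entirely within the thorax",
        ),
        CuratedEntailment(
            s("iliac colon"), PELVIC_SEGMENT_S, True,
            "iliac colon discussion: it is also within the pelvic segment of trunk",
        ),
        CuratedEntailment(
            s("iliac colon"), INTRA_ABDOMINAL_PROPER, True,
            "iliac colon discussion: it is an intra-abdominal proper structure",
        ),
        CuratedEntailment(
            s("perineum"), PELVIC_SEGMENT_S, True,
            "pelvic segment definition: the pelvic segment includes the entire perineum",
        ),
        CuratedEntailment(
            ABDOMEN_PROPER_REGION, ABDOMEN_REGION, True,
            "complex clinical regions: the clinical abdomen proper is a sub-volume of the "
            "clinical 'Abdomen'",
        ),
        CuratedEntailment(
            INTRA_ABDOMINOPELVIC, ABDOMEN_REGION, True,
            "single-synonym allocation: 'Abdomen' = intra-abdominopelvic structure and/or "
            "anterior abdominal wall",
        ),
        CuratedEntailment(
            "X-ct-of-abdomen", "X-ct-of-abdomen-and-pelvis", True,
            "cross-sectional segment definitions: the abdominopelvic cross-section combines the "
            "abdominal and pelvic cross-sections",
        ),
    ]


def negative_suite() -> list:
    """Subsumptions the published model explicitly rules out."""
    m = build_trunk_model()
    s = lambda label: structure_of(m, label)  # noqa: E731
    return [
        CuratedEntailment(
            s("anal canal"), INTRA_ABDOMINOPELVIC, False,
            "containment analysis: the anal canal is not entirely contained within the "
            "abdominopelvic cavity",
        ),
        CuratedEntailment(
            s("large intestine"), CONTENT_ABDOMINOPELVIC, False,
            "containment analysis: as a consequence neither is the entire large intestine",
        ),
        CuratedEntailment(
            s("large intestine"), INTRA_ABDOMINOPELVIC, False,
            "containment analysis: the entire large intestine extends below the pelvic "
            "diaphragm",
        ),
        CuratedEntailment(
            s("aorta"), INTRA_THORACIC, False,
            "meronymic-reasoning exemplar: the aorta cannot be subordinate to the thoracic structure "
            "as its abdominal segment lies outside",
        ),
        CuratedEntailment(
            s("aorta"), THORACIC_CAVITY, False,
            "meronymic-reasoning exemplar: same containment-law violation, stated against the cavity",
        ),
        CuratedEntailment(
            s("pelvic wall"), INTRA_ABDOMINOPELVIC, False,
            "intra- convention: 'intra' comprises the space and content but excludes the "
            "walls that delineate the space",
        ),
        CuratedEntailment(
            s("anterior abdominal wall"), INTRA_ABDOMINOPELVIC, False,
            "intra- convention: the anterior abdominal wall is a boundary, not content",
        ),
        CuratedEntailment(
            s("lumbar vertebral column"), ABDOMEN_REGION, False,
            "clinical-usage review: clinicians would not consider disorders of the lumbar "
            "vertebrae to fall within the 'abdomen'",
        ),
        CuratedEntailment(
            s("perineum"), PELVIC_REGION, False,
            "pelvic-region comparison: the pelvic region excludes the perineum "
            "external genitalia",
        ),
        CuratedEntailment(
            s("external genitalia"), PELVIC_REGION, False,
            "pelvic-region comparison: ... and external genitalia",
        ),
        CuratedEntailment(
            s("external genitalia"), PELVIC_XS_S, False,
            "pelvic cross-section definition: the pelvic cross-section includes part but not "
            "necessarily the entire external genitalia — no axiom is stated",
        ),
        CuratedEntailment(
            entire_of(m, "liver"), m.triplets["liver"].part, False,
            "meronymic-reasoning exemplar: a 'liver part' is not instantiated by any liver",
        ),
        CuratedEntailment(
            m.triplets["liver"].part, entire_of(m, "liver"), False,
            "meronymic-reasoning exemplar: nor conversely; Entire and Part are distinct classes",
        ),
        CuratedEntailment(
            s("uterus"), ABDOMEN_PROPER_SEGMENT_S, False,
            "gravid-uterus caveat: the uterus normally resides in the true pelvis, outside the "
            "abdomen proper",
        ),
        CuratedEntailment(
            ABDOMEN_REGION, ABDOMEN_PROPER_REGION, False,
            "complex clinical regions: 'Abdomen' includes the intra-pelvic structures that "
            "'Abdomen proper' excludes",
        ),
    ]


# ---------------------------------------------------------------------------
# Edit scenarios for the impact-QA loop
# ---------------------------------------------------------------------------

def scenario_remove_iliac_colon_placement(model: TrunkModel) -> Ontology:
    """Delete the axiom placing the iliac colon in the pelvic segment."""
    edited = model.ontology.copy()
    edited.remove_axiom(subclass_of(
        model.triplets["iliac colon"].entire,
        some(REGIONAL_PART_OF, model.triplets["pelvic segment of trunk"].entire),
    ))
    return edited


def scenario_misplace_uterus(model: TrunkModel) -> Ontology:
    """Erroneously assert the uterus into the abdomen proper segment.

    Simulates the modelling error the iterative QA loop is designed to catch:
    the gained subsumptions include disorder-of-uterus under
    disorder-of-abdomen-proper, and the curated negative suite flags the
    misplacement.
    """
    edited = model.ontology.copy()
    assert_part(
        edited,
        model.triplets["uterus"].entire,
        model.triplets["abdomen proper segment of trunk"].entire,
        "constitutional",
    )
    return edited


# ---------------------------------------------------------------------------
# Asserted placement graph (containment-law test discipline)
# ---------------------------------------------------------------------------

def asserted_placement_graph(model: TrunkModel):
    """Directed graph of asserted placements between fixture concepts.

    Edges: (i) for each part axiom between Entire classes, an edge between
    the corresponding Structure classes; (ii) every asserted named-to-named
    SubClassOf.  Classified structure-to-structure subsumption must coincide
    with reachability here: a structure sits under another structure only
    when an asserted placement path exists.
    """
    import networkx as nx

    from .core_model import AxiomKind, Existential
    from .sep_builder import PART_KINDS

    part_roles = set(PART_KINDS.values())
    entire_to_structure = {
        t.entire: t.structure for t in model.triplets.values()
    }
    g = nx.DiGraph()
    g.add_nodes_from(model.ontology.concepts)
    for ax in model.ontology.axioms:
        if ax.kind is not AxiomKind.SUBCLASS_OF:
            continue
        if isinstance(ax.left, Named) and isinstance(ax.right, Named):
            g.add_edge(ax.left.concept, ax.right.concept)
        elif (
            isinstance(ax.left, Named)
            and isinstance(ax.right, Existential)
            and ax.right.role in part_roles
            and isinstance(ax.right.filler, Named)
        ):
            child = entire_to_structure.get(ax.left.concept)
            parent = entire_to_structure.get(ax.right.filler.concept)
            if child and parent:
                g.add_edge(child, parent)
    return g
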