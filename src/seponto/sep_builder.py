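"""Axiom patterns for meronymic (part-whole) modelling of anatomy.

The SEP pattern gives every anatomical entity three classes:

* ``Entire X`` -- instantiated by whole entities of the kind;
* ``X part``   -- instantiated by proper parts of such entities;
* ``Structure of X`` -- the aggregation, entire and/or any part, defined as
  ``EquivalentTo 'all or part of' some 'Entire X'``.

Part-whole placement is asserted between *Entire* classes with one of the
sub-properties of ``proper-part-of`` (regional / constitutional / systemic);
classification then propagates the placement to the Part and Structure
classes through the role hierarchy and the transitivity chain on
``all-or-part-of``.  The "all of" (reflexive) reading of ``all-or-part-of``
is captured by the explicit axiom ``Entire X ⊑ Structure of X`` rather than
a reflexive role, which keeps the rule engine free of reflexivity handling.

A second pattern covers body cavities: ``Intra-X structure`` is the primitive
aggregation of a cavity and its contents (the space-and-contents reading of
"intra-"), deliberately excluding the cavity walls.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core_model import (
    Axiom,
    ConceptRef,
    DuplicateIdError,
    Named,
    Ontology,
    OntologyError,
    Role,
    RoleChain,
    SemanticClass,
    UnknownIdError,
    conj,
    equivalent,
    some,
    subclass_of,
)

# Canonical role ids of the meronymy role box.
ALL_OR_PART_OF = "all-or-part-of"
PROPER_PART_OF = "proper-part-of"
REGIONAL_PART_OF = "regional-part-of"
CONSTITUTIONAL_PART_OF = "constitutional-part-of"
SYSTEMIC_PART_OF = "systemic-part-of"
FINDING_SITE = "finding-site"
PROCEDURE_SITE = "procedure-site"

PART_KINDS = {
    "regional": REGIONAL_PART_OF,
    "constitutional": CONSTITUTIONAL_PART_OF,
    "systemic": SYSTEMIC_PART_OF,
}

#: Root concepts for dependent (site-defined) hierarchies.
DISORDER_ROOT = "X-disorder"
PROCEDURE_ROOT = "X-procedure"


def add_meronymy_roles(ont: Ontology) -> Ontology:
    """Declare the standard role box used by the SEP pattern.

    ``all-or-part-of`` and ``proper-part-of`` are transitive; the three
    specific part relations are non-transitive sub-properties of
    ``proper-part-of``; the two site relations are independent.
    """
    ont.add_role(Role(ALL_OR_PART_OF, "All or part of", transitive=True))
    ont.add_role(
        Role(PROPER_PART_OF, "Proper part of", parent=ALL_OR_PART_OF, transitive=True)
    )
    ont.add_role(Role(REGIONAL_PART_OF, "Regional part of", parent=PROPER_PART_OF))
    ont.add_role(
        Role(CONSTITUTIONAL_PART_OF, "Constitutional part of", parent=PROPER_PART_OF)
    )
    ont.add_role(Role(SYSTEMIC_PART_OF, "Systemic part of", parent=PROPER_PART_OF))
    ont.add_role(Role(FINDING_SITE, "Finding site"))
    ont.add_role(Role(PROCEDURE_SITE, "Procedure site"))
    # anything that is all or part of a proper part is itself a proper part;
    # this (regular) chain is what classifies Structure(child) under
    # Part(parent), e.g. lobe-of-liver structures under "Liver part"
    ont.add_chain(RoleChain((ALL_OR_PART_OF, PROPER_PART_OF), PROPER_PART_OF))
    return ont


def _slug(label: str) -> str:
    return label.lower().replace(" ", "-").replace("/", "-")


@dataclass(frozen=True)
class SEPTriplet:
    """The (entire, part, structure) concept trio for one anatomical entity."""

    entire: str
    part: str
    structure: str
    axioms: tuple


def make_sep_triplet(
    ont: Ontology,
    label: str,
    ids: tuple = None,
    *,
    names: tuple = None,
    structure_preferred: str = None,
    structure_class: SemanticClass = SemanticClass.STRUCTURE,
) -> SEPTriplet:
    """Add the three SEP concepts and their defining axioms for *label*.

    ``ids`` optionally fixes the (entire, part, structure) ids — used when a
    released identifier exists for the structure concept; otherwise local
    ``X-`` ids derived from the label are used.  ``names`` optionally
    overrides the three FSN stems (entire, part, structure) where released
    terminology differs from the default ``Entire <label>`` / ``<label>
    part`` / ``Structure of <label>`` scheme.
    """
    if not label:
        raise OntologyError("SEP triplet label must be non-empty")
    slug = _slug(label)
    if ids is None:
        ids = (f"X-{slug}-e", f"X-{slug}-p", f"X-{slug}-s")
    entire_id, part_id, structure_id = ids
    if names is None:
        cap = label[0].upper() + label[1:]
        names = (f"Entire {label}", f"{cap} part", f"Structure of {label}")
    entire_name, part_name, structure_name = names

    for cid, name, sclass, primitive in (
        (entire_id, entire_name, SemanticClass.ENTIRE, True),
        (part_id, part_name, SemanticClass.PART, False),
        (structure_id, structure_name, structure_class, False),
    ):
        preferred = name
        if cid == structure_id and structure_preferred is not None:
            preferred = structure_preferred
        ont.add_concept(
            ConceptRef(
                id=cid,
                fsn=f"{name} (body structure)",
                preferred_term=preferred,
                primitive=primitive,
                semantic_class=sclass,
            )
        )

    axioms = (
        equivalent(structure_id, some(ALL_OR_PART_OF, entire_id)),
        equivalent(part_id, some(PROPER_PART_OF, entire_id)),
        subclass_of(entire_id, structure_id),
        subclass_of(part_id, structure_id),
    )
    ont.add_axioms(axioms)
    return SEPTriplet(entire_id, part_id, structure_id, axioms)


def assert_part(
    ont: Ontology, child_entire: str, parent_entire: str, kind: str
) -> Ontology:
    """Assert that the *child* entity is a <kind> part of the *parent* entity.

    Adds ``Entire child ⊑ ∃<kind>-part-of.Entire parent``; after
    classification, ``Structure(child) ⊑ Part(parent) ⊑ Structure(parent)``.
    """
    if kind not in PART_KINDS:
        raise OntologyError(
            f"unknown part kind {kind!r}; expected one of {sorted(PART_KINDS)}"
        )
    for cid in (child_entire, parent_entire):
        if cid not in ont.concepts:
            raise UnknownIdError(f"unknown concept {cid!r}")
    return ont.add_axiom(
        subclass_of(child_entire, some(PART_KINDS[kind], parent_entire))
    )


def make_cavity_wall_content(
    ont: Ontology,
    label: str,
    *,
    ids: tuple = None,
    cavity_fsn: str = None,
    cavity_preferred: str = None,
    intra_fsn: str = None,
) -> tuple:
    """Add the cavity / content / intra- pattern for a cavity *label*.

    Creates ``Structure of <label> cavity``, ``Content of <label> cavity``
    and the primitive aggregation ``Intra-<label> structure`` with both the
    cavity and the content subsumed by the intra- concept.  The walls that
    delineate the space are *not* subsumed: "intra-" means space and contents
    only.  ``ids`` optionally fixes the (cavity, content, intra) ids, and the
    ``*_fsn`` overrides accommodate released names that deviate from the
    default scheme.  Returns (cavity id, content id, intra id, axioms).
    """
    if not label:
        raise OntologyError("cavity label must be non-empty")
    slug = _slug(label)
    if ids is None:
        ids = (f"X-{slug}-cavity", f"X-{slug}-content", f"X-intra-{slug}")
    cavity_id, content_id, intra_id = ids
    cavity_name = cavity_fsn or f"Structure of {label} cavity"
    intra_name = intra_fsn or f"Intra-{label} structure"
    for cid, name, preferred, sclass in (
        (cavity_id, cavity_name, cavity_preferred or cavity_name, SemanticClass.CAVITY),
        (content_id, f"Content of {label} cavity", None, SemanticClass.CONTENT),
        (intra_id, intra_name, None, SemanticClass.STRUCTURE),
    ):
        if cid in ont.concepts:
            raise DuplicateIdError(f"id {cid!r} is already declared")
        ont.add_concept(
            ConceptRef(
                id=cid,
                fsn=f"{name} (body structure)",
                preferred_term=preferred or name,
                primitive=True,
                semantic_class=sclass,
            )
        )
    axioms = (
        subclass_of(cavity_id, intra_id),
        subclass_of(content_id, intra_id),
    )
    ont.add_axioms(axioms)
    return cavity_id, content_id, intra_id, axioms


def ensure_dependent_roots(ont: Ontology) -> Ontology:
    if DISORDER_ROOT not in ont.concepts:
        ont.add_concept(
            ConceptRef(
                id=DISORDER_ROOT,
                fsn="Disorder (disorder)",
                preferred_term="Disorder",
                primitive=True,
                semantic_class=SemanticClass.DISORDER,
            )
        )
    if PROCEDURE_ROOT not in ont.concepts:
        ont.add_concept(
            ConceptRef(
                id=PROCEDURE_ROOT,
                fsn="Procedure (procedure)",
                preferred_term="Procedure",
                primitive=True,
                semantic_class=SemanticClass.PROCEDURE,
            )
        )
    return ont


def define_dependent(
    ont: Ontology,
    label: str,
    site: str,
    dependent_kind: str = "disorder",
    *,
    concept_id: str = None,
) -> str:
    """Add a fully defined disorder or procedure located at *site*.

    The new concept is ``EquivalentTo <root> and 'finding site' some <site>``
    (``procedure site`` for procedures), so subsumption between dependents
    follows the subsumption of their sites.  Returns the new concept id.
    """
    if dependent_kind == "disorder":
        root, role, tag, sclass = (
            DISORDER_ROOT, FINDING_SITE, "disorder", SemanticClass.DISORDER,
        )
    elif dependent_kind == "procedure":
        root, role, tag, sclass = (
            PROCEDURE_ROOT, PROCEDURE_SITE, "procedure", SemanticClass.PROCEDURE,
        )
    else:
        raise OntologyError(
            f"unknown dependent kind {dependent_kind!r}; "
            "expected 'disorder' or 'procedure'"
        )
    if site not in ont.concepts:
        raise UnknownIdError(f"unknown site concept {site!r}")
    ensure_dependent_roots(ont)
    cid = concept_id or f"X-{_slug(label)}"
    ont.add_concept(
        ConceptRef(
            id=cid,
            fsn=f"{label} ({tag})",
            preferred_term=label,
            primitive=False,
            semantic_class=sclass,
        )
    )
    ont.add_axiom(
        equivalent(cid, conj(Named(root), some(role, site)))
    )
    return cid
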