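"""Domain model for EL ontologies of anatomical concepts.

Concepts, roles (object properties with hierarchy and chains), class
expressions restricted to the OWL 2 EL fragment (names, conjunction,
existential restriction), axioms, and the :class:`Ontology` container that
assembles them.

Expression equality is structural: conjunction operands are kept in a
frozenset, so conjunction is commutative, associative and idempotent under
``==``.  Ontology equality ignores the insertion order of concepts and
axioms, which makes assembly order-independent.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Union


class OntologyError(Exception):
    """Base class for ontology assembly and lookup errors."""


class DuplicateIdError(OntologyError):
    """A concept or role id was declared twice."""


class DuplicateSynonymError(OntologyError):
    """A policed preferred term was attached to a second concept."""


class UnknownIdError(OntologyError):
    """An axiom or query referenced an undeclared concept or role id."""


class SemanticClass(str, enum.Enum):
    """Coarse editorial category of a concept, used for filtering reports."""

    ENTIRE = "entire"
    PART = "part"
    STRUCTURE = "structure"
    CAVITY = "cavity"
    WALL = "wall"
    SEGMENT = "segment"
    CROSS_SECTION = "cross_section"
    CLINICAL_REGION = "clinical_region"
    CONTENT = "content"
    DISORDER = "disorder"
    PROCEDURE = "procedure"
    OTHER = "other"


#: Preferred terms that may be attached to at most one concept per ontology.
#: SNOMED International resolved the polysemy of "abdomen" by designating the
#: bare token to a single concept; the other near-variant clinical regions use
#: explicit concatenated preferred terms.
POLICED_PREFERRED_TERMS = ("Abdomen",)


# ---------------------------------------------------------------------------
# Expressions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Named:
    """A named class (reference to a declared concept id)."""

    concept: str


@dataclass(frozen=True)
class Conjunction:
    """Intersection of two or more class expressions (order-insensitive)."""

    operands: frozenset

    def __post_init__(self):
        if not self.operands:
            raise ValueError("conjunction must have at least one operand")


@dataclass(frozen=True)
class Existential:
    """Existential restriction ``role some filler``."""

    role: str
    filler: "Expression"


Expression = Union[Named, Conjunction, Existential]


def conj(*operands: Expression) -> Expression:
    """Build a conjunction, flattening nested conjunctions.

    A single-operand conjunction collapses to the operand itself.
    """
    flat: set = set()
    for op in operands:
        if isinstance(op, Conjunction):
            flat |= op.operands
        else:
            flat.add(op)
    if not flat:
        raise ValueError("conjunction must have at least one operand")
    if len(flat) == 1:
        return next(iter(flat))
    return Conjunction(frozenset(flat))


def some(role: str, filler: Union[Expression, str]) -> Existential:
    """Build an existential restriction; a string filler means a named class."""
    if isinstance(filler, str):
        filler = Named(filler)
    return Existential(role, filler)


def expression_names(expr: Expression) -> set:
    """All concept ids referenced by *expr*."""
    if isinstance(expr, Named):
        return {expr.concept}
    if isinstance(expr, Existential):
        return expression_names(expr.filler)
    out: set = set()
    for op in expr.operands:
        out |= expression_names(op)
    return out


def expression_roles(expr: Expression) -> set:
    """All role ids referenced by *expr*."""
    if isinstance(expr, Named):
        return set()
    if isinstance(expr, Existential):
        return {expr.role} | expression_roles(expr.filler)
    out: set = set()
    for op in expr.operands:
        out |= expression_roles(op)
    return out


def canonical(expr: Expression) -> str:
    """Deterministic canonical string of an expression.

    Structurally equal expressions always canonicalise identically;
    conjunction operands are sorted by their own canonical form.
    """
    if isinstance(expr, Named):
        return expr.concept
    if isinstance(expr, Existential):
        return f"some({expr.role} {canonical(expr.filler)})"
    inner = " ".join(sorted(canonical(op) for op in expr.operands))
    return f"and({inner})"


# ---------------------------------------------------------------------------
# Axioms
# ---------------------------------------------------------------------------

class AxiomKind(str, enum.Enum):
    SUBCLASS_OF = "subclass_of"
    EQUIVALENT = "equivalent"


@dataclass(frozen=True)
class Axiom:
    """A SubClassOf or EquivalentClasses statement.

    Equivalence axioms are restricted to the ``name EquivalentTo definition``
    form: the left side must be a :class:`Named` expression.
    """

    kind: AxiomKind
    left: Expression
    right: Expression

    def __post_init__(self):
        if self.kind is AxiomKind.EQUIVALENT and not isinstance(self.left, Named):
            raise ValueError("equivalent axioms must have a named left side")


def subclass_of(left: Union[Expression, str], right: Union[Expression, str]) -> Axiom:
    if isinstance(left, str):
        left = Named(left)
    if isinstance(right, str):
        right = Named(right)
    return Axiom(AxiomKind.SUBCLASS_OF, left, right)


def equivalent(name: Union[Named, str], definition: Expression) -> Axiom:
    if isinstance(name, str):
        name = Named(name)
    return Axiom(AxiomKind.EQUIVALENT, name, definition)


# ---------------------------------------------------------------------------
# Concepts and roles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConceptRef:
    """A named concept with its terminology descriptions.

    ``primitive`` concepts carry only SubClassOf axioms; non-primitive
    (sufficiently defined) concepts have exactly one EquivalentClasses axiom
    whose left side is their name.  The fully specified name (``fsn``) keeps
    its semantic-tag suffix, e.g. ``"Liver structure (body structure)"``.
    """

    id: str
    fsn: str
    preferred_term: str = ""
    synonyms: tuple = ()
    primitive: bool = True
    semantic_class: SemanticClass = SemanticClass.OTHER

    def __post_init__(self):
        if not self.id:
            raise ValueError("concept id must be non-empty")
        if not self.fsn:
            raise ValueError(f"concept {self.id!r} must have an fsn")


@dataclass(frozen=True)
class Role:
    """An object property, optionally transitive, in a simple hierarchy."""

    id: str
    name: str
    parent: Optional[str] = None
    transitive: bool = False


@dataclass(frozen=True)
class RoleChain:
    """A complex role inclusion ``lhs[0] o lhs[1] SubPropertyOf rhs``.

    Transitivity is encoded separately on :class:`Role`; the reasoner compiles
    it to the chain ``r o r -> r``.
    """

    lhs: tuple
    rhs: str

    def __post_init__(self):
        if len(self.lhs) != 2:
            raise ValueError("role chains are binary (r1 o r2 -> s)")


# ---------------------------------------------------------------------------
# Ontology
# ---------------------------------------------------------------------------

@dataclass
class Ontology:
    """Mutable assembly of concepts, roles, chains and axioms.

    ``add_*`` methods validate invariants and return ``self`` so calls can be
    chained.  Equality is structural and order-insensitive.
    """

    concepts: dict = field(default_factory=dict)
    roles: dict = field(default_factory=dict)
    chains: list = field(default_factory=list)
    axioms: list = field(default_factory=list)

    # -- declaration ---------------------------------------------------

    def add_concept(self, c: ConceptRef) -> "Ontology":
        if c.id in self.concepts or c.id in self.roles:
            raise DuplicateIdError(f"id {c.id!r} is already declared")
        for other in self.concepts.values():
            if other.fsn == c.fsn:
                raise DuplicateIdError(
                    f"fsn {c.fsn!r} of {c.id!r} already used by {other.id!r}"
                )
        for term in POLICED_PREFERRED_TERMS:
            if c.preferred_term == term:
                holder = self._preferred_term_holder(term)
                if holder is not None:
                    raise DuplicateSynonymError(
                        f"preferred term {term!r} is already attached to "
                        f"{holder.id!r} and may not also name {c.id!r}"
                    )
        self.concepts[c.id] = c
        return self

    def _preferred_term_holder(self, term: str) -> Optional[ConceptRef]:
        for other in self.concepts.values():
            if other.preferred_term == term:
                return other
        return None

    def add_role(self, r: Role) -> "Ontology":
        if r.id in self.roles or r.id in self.concepts:
            raise DuplicateIdError(f"id {r.id!r} is already declared")
        self.roles[r.id] = r
        self._check_role_acyclic(r)
        return self

    def _check_role_acyclic(self, r: Role) -> None:
        seen = set()
        cur: Optional[str] = r.id
        while cur is not None:
            if cur in seen:
                raise OntologyError(f"role hierarchy cycle through {cur!r}")
            seen.add(cur)
            parent = self.roles.get(cur)
            cur = parent.parent if parent is not None else None

    def add_chain(self, chain: RoleChain) -> "Ontology":
        for rid in (*chain.lhs, chain.rhs):
            if rid not in self.roles:
                raise UnknownIdError(f"chain references undeclared role {rid!r}")
        if chain not in self.chains:
            self.chains.append(chain)
        return self

    # -- axioms --------------------------------------------------------

    def add_axiom(self, ax: Axiom) -> "Ontology":
        for cid in expression_names(ax.left) | expression_names(ax.right):
            if cid not in self.concepts:
                raise UnknownIdError(f"axiom references undeclared concept {cid!r}")
        for rid in expression_roles(ax.left) | expression_roles(ax.right):
            if rid not in self.roles:
                raise UnknownIdError(f"axiom references undeclared role {rid!r}")
        if ax.kind is AxiomKind.EQUIVALENT:
            name = ax.left.concept  # type: ignore[union-attr]
            for other in self.axioms:
                if (
                    other.kind is AxiomKind.EQUIVALENT
                    and other.left == ax.left
                    and other != ax
                ):
                    raise OntologyError(
                        f"concept {name!r} already has an equivalence definition"
                    )
        if ax not in self.axioms:  # structural duplicates ignored idempotently
            self.axioms.append(ax)
        return self

    def add_axioms(self, axioms: Iterable[Axiom]) -> "Ontology":
        for ax in axioms:
            self.add_axiom(ax)
        return self

    def remove_axiom(self, ax: Axiom) -> "Ontology":
        """Remove a stated axiom (used by edit/impact scenarios)."""
        try:
            self.axioms.remove(ax)
        except ValueError:
            raise OntologyError("axiom is not stated in this ontology") from None
        return self

    # -- queries -------------------------------------------------------

    def concept(self, cid: str) -> ConceptRef:
        try:
            return self.concepts[cid]
        except KeyError:
            raise UnknownIdError(f"unknown concept {cid!r}") from None

    def require_role(self, rid: str) -> Role:
        try:
            return self.roles[rid]
        except KeyError:
            raise UnknownIdError(f"unknown role {rid!r}") from None

    def equivalence_definition(self, cid: str) -> Optional[Axiom]:
        for ax in self.axioms:
            if ax.kind is AxiomKind.EQUIVALENT and ax.left == Named(cid):
                return ax
        return None

    def set_primitive_flags(self) -> "Ontology":
        """Align each concept's ``primitive`` flag with its axioms."""
        defined = {
            ax.left.concept
            for ax in self.axioms
            if ax.kind is AxiomKind.EQUIVALENT and isinstance(ax.left, Named)
        }
        for cid, c in list(self.concepts.items()):
            prim = cid not in defined
            if c.primitive != prim:
                self.concepts[cid] = replace(c, primitive=prim)
        return self

    def validate(self) -> None:
        """Check cross-cutting invariants; raises OntologyError on failure."""
        defined: dict = {}
        for ax in self.axioms:
            if ax.kind is AxiomKind.EQUIVALENT:
                name = ax.left.concept  # type: ignore[union-attr]
                if name in defined:
                    raise OntologyError(
                        f"concept {name!r} has more than one equivalence definition"
                    )
                defined[name] = ax
        for cid, c in self.concepts.items():
            if not c.primitive and cid not in defined:
                raise OntologyError(
                    f"non-primitive concept {cid!r} lacks an equivalence definition"
                )
            if c.primitive and cid in defined:
                raise OntologyError(
                    f"primitive concept {cid!r} carries an equivalence definition"
                )

    # -- equality ------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Ontology):
            return NotImplemented
        return (
            self.concepts == other.concepts
            and self.roles == other.roles
            and set(self.chains) == set(other.chains)
            and set(self.axioms) == set(other.axioms)
        )

    def copy(self) -> "Ontology":
        out = Ontology()
        out.concepts = dict(self.concepts)
        out.roles = dict(self.roles)
        out.chains = list(self.chains)
        out.axioms = list(self.axioms)
        return out
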