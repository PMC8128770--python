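"""Seeded random EL ontologies and an independent entailment oracle.

The generator produces small, valid EL ontologies (names, conjunctions,
existential restrictions; random role hierarchy with a configurable fraction
of transitive roles) reproducibly from a seed.  The oracle decides
subsumption by building the canonical model of the ontology with a chase:
one element per named concept plus one per existential filler expression,
labels and role edges grown by unindexed fixpoint iteration over the
original (un-normalized) axioms.  ``A ⊑ B`` holds iff the element introduced
for ``A`` satisfies ``B`` in the final model.

The oracle deliberately shares no code with the completion-rule reasoner in
:mod:`seponto.el_reasoner` — it exists to witness that module's soundness
and completeness, so it uses a different algorithm on a different input
representation and is kept simple rather than fast.  A size guard protects
against accidental blow-up; callers that genuinely need a larger closure
(the impact-QA cross-check) must raise it explicitly.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .core_model import (
    AxiomKind,
    ConceptRef,
    Conjunction,
    Existential,
    Named,
    Ontology,
    Role,
    SemanticClass,
    UnknownIdError,
    canonical,
    equivalent,
    subclass_of,
)


@dataclass(frozen=True)
class GenConfig:
    """Parameters of the random ontology generator."""

    n_concepts: int = 8
    n_roles: int = 2
    n_axioms: int = 12
    p_existential: float = 0.4
    p_conjunction: float = 0.3
    max_depth: int = 2
    transitive_fraction: float = 0.5
    p_equivalent: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_concepts <= 0 or self.n_roles < 0 or self.n_axioms < 0:
            raise ValueError("counts must be positive")
        for p in (
            self.p_existential,
            self.p_conjunction,
            self.transitive_fraction,
            self.p_equivalent,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.max_depth < 0:
            raise ValueError("max_depth must be non-negative")


def generate(cfg: GenConfig) -> Ontology:
    """Generate a valid EL ontology; identical config+seed → identical output."""
    cfg.validate()
    rng = random.Random(cfg.seed)
    ont = Ontology()
    concept_ids = [f"C{i}" for i in range(cfg.n_concepts)]
    role_ids = [f"r{i}" for i in range(cfg.n_roles)]

    for cid in concept_ids:
        ont.add_concept(
            ConceptRef(
                id=cid,
                fsn=f"{cid} (synthetic)",
                preferred_term=cid,
                semantic_class=SemanticClass.OTHER,
            )
        )
    for i, rid in enumerate(role_ids):
        parent = rng.choice(role_ids[:i]) if i and rng.random() < 0.5 else None
        ont.add_role(
            Role(
                id=rid,
                name=f"role {rid}",
                parent=parent,
                transitive=rng.random() < cfg.transitive_fraction,
            )
        )

    def rand_expr(depth: int):
        roll = rng.random()
        if depth > 0 and role_ids and roll < cfg.p_existential:
            return Existential(rng.choice(role_ids), rand_expr(depth - 1))
        if depth > 0 and roll < cfg.p_existential + cfg.p_conjunction:
            ops = frozenset(
                rand_expr(depth - 1) for _ in range(rng.randint(2, 3))
            )
            if len(ops) == 1:
                return next(iter(ops))
            return Conjunction(ops)
        return Named(rng.choice(concept_ids))

    defined: set = set()
    for _ in range(cfg.n_axioms):
        if rng.random() < cfg.p_equivalent:
            candidates = [c for c in concept_ids if c not in defined]
            if candidates:
                name = rng.choice(candidates)
                rhs = rand_expr(cfg.max_depth)
                if rhs != Named(name):
                    ont.add_axiom(equivalent(name, rhs))
                    defined.add(name)
                continue
        lhs = rand_expr(cfg.max_depth)
        rhs = rand_expr(cfg.max_depth)
        if lhs != rhs:
            ont.add_axiom(subclass_of(lhs, rhs))
    ont.set_primitive_flags()
    return ont


# ---------------------------------------------------------------------------
# Canonical-model oracle
# ---------------------------------------------------------------------------

class OracleSizeError(Exception):
    """The ontology exceeds the oracle's size guard."""


class _Chase:
    """Canonical model of an EL ontology, built by naive fixpoint chase."""

    def __init__(self, ont: Ontology):
        self.ont = ont
        self.labels: dict = {}   # element key -> set of concept ids
        self.edges: dict = {}    # (element, role) -> set of elements
        self.super_roles = self._role_closure()
        self.chains = [(c.lhs[0], c.lhs[1], c.rhs) for c in ont.chains]
        for rid, role in ont.roles.items():
            if role.transitive:
                triple = (rid, rid, rid)
                if triple not in self.chains:
                    self.chains.append(triple)
        for cid in ont.concepts:
            self.labels[cid] = {cid}
        self._directed = []
        for ax in ont.axioms:
            self._directed.append((ax.left, ax.right))
            if ax.kind is AxiomKind.EQUIVALENT:
                self._directed.append((ax.right, ax.left))
        self._run()

    def _role_closure(self) -> dict:
        out = {}
        for rid in self.ont.roles:
            supers = set()
            cur = rid
            while cur is not None and cur not in supers:
                supers.add(cur)
                role = self.ont.roles.get(cur)
                cur = role.parent if role is not None else None
            out[rid] = supers
        return out

    # element bookkeeping ------------------------------------------------

    def _element_for(self, filler) -> str:
        if isinstance(filler, Named):
            return filler.concept
        key = f"@{canonical(filler)}"
        if key not in self.labels:
            self.labels[key] = set()
            self._apply(key, filler)
        return key

    def _add_edge(self, src: str, role: str, tgt: str) -> bool:
        changed = False
        for s in self.super_roles.get(role, {role}):
            bucket = self.edges.setdefault((src, s), set())
            if tgt not in bucket:
                bucket.add(tgt)
                changed = True
        return changed

    # satisfaction and application --------------------------------------

    def _satisfies(self, elem: str, expr) -> bool:
        if isinstance(expr, Named):
            return expr.concept in self.labels[elem]
        if isinstance(expr, Conjunction):
            return all(self._satisfies(elem, op) for op in expr.operands)
        for tgt in self.edges.get((elem, expr.role), ()):
            if self._satisfies(tgt, expr.filler):
                return True
        return False

    def _apply(self, elem: str, expr) -> bool:
        if isinstance(expr, Named):
            if expr.concept not in self.labels[elem]:
                self.labels[elem].add(expr.concept)
                return True
            return False
        if isinstance(expr, Conjunction):
            changed = False
            for op in expr.operands:
                changed |= self._apply(elem, op)
            return changed
        tgt = self._element_for(expr.filler)
        changed = self._add_edge(elem, expr.role, tgt)
        if isinstance(expr.filler, Conjunction):
            changed |= self._apply(tgt, expr.filler)
        return changed

    # the chase ----------------------------------------------------------

    def _run(self) -> None:
        changed = True
        while changed:
            changed = False
            for elem in list(self.labels):
                for left, right in self._directed:
                    if self._satisfies(elem, left):
                        if self._apply(elem, right):
                            changed = True
            for r1, r2, s in self.chains:
                for (src, role), mids in list(self.edges.items()):
                    if role != r1:
                        continue
                    for mid in list(mids):
                        for tgt in list(self.edges.get((mid, r2), ())):
                            if self._add_edge(src, s, tgt):
                                changed = True

    def entails(self, sub: str, super_expr) -> bool:
        return self._satisfies(sub, super_expr)


def _guard(ont: Ontology, max_concepts: int) -> None:
    if len(ont.concepts) > max_concepts:
        raise OracleSizeError(
            f"ontology has {len(ont.concepts)} concepts; oracle guard is "
            f"{max_concepts} (pass max_concepts explicitly to override)"
        )


def naive_entails(ont: Ontology, sub: str, super_: str, *, max_concepts: int = 15) -> bool:
    """Brute-force subsumption test, independent of the main reasoner."""
    _guard(ont, max_concepts)
    for cid in (sub, super_):
        if cid not in ont.concepts:
            raise UnknownIdError(f"unknown concept {cid!r}")
    return _Chase(ont).entails(sub, Named(super_))


def naive_closure(ont: Ontology, *, max_concepts: int = 15) -> frozenset:
    """All entailed (sub, super) pairs over declared concepts, incl. reflexive."""
    _guard(ont, max_concepts)
    chase = _Chase(ont)
    declared = set(ont.concepts)
    return frozenset(
        (a, b)
        for a in declared
        for b in chase.labels[a]
        if b in declared
    )
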