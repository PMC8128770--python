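"""EL classification: normalization, completion-rule saturation, taxonomy.

The classifier implements the standard polynomial procedure for the OWL 2 EL
fragment with role hierarchies and (regular) role chains:

1. axioms are rewritten into four normal forms over named classes
   (``A ⊑ B``, ``A1 ⊓ … ⊓ An ⊑ B``, ``A ⊑ ∃r.B``, ``∃r.A ⊑ B``), introducing
   deterministically named fresh classes for complex subexpressions;
2. the subsumption relation is saturated with the completion rules
   (conjunction, existential introduction, existential-on-the-left,
   role hierarchy, role composition); transitivity is compiled to the
   chain ``r ∘ r ⊑ r``;
3. the closure restricted to declared (non-fresh) concepts is reduced to a
   direct-parent DAG over equivalence classes (transitive reduction).

Saturation is a worklist least-fixpoint; at the fixture scales in scope
(<10^3 concepts) no goal-directed optimisation is needed.
"""

from __future__ import annotations

import hashlib
from collections import deque
from dataclasses import dataclass, field

import networkx as nx

from .core_model import (
    Axiom,
    AxiomKind,
    Conjunction,
    Existential,
    Named,
    Ontology,
    RoleChain,
    UnknownIdError,
    canonical,
)

FRESH_PREFIX = "N-"


def is_fresh(cid: str) -> bool:
    return cid.startswith(FRESH_PREFIX)


def fresh_name(expr) -> str:
    """Deterministic fresh class name for a complex expression."""
    digest = hashlib.sha1(canonical(expr).encode("utf-8")).hexdigest()[:12]
    return f"{FRESH_PREFIX}{digest}"


class NonELConstructError(Exception):
    """An expression outside the EL fragment reached the reasoner."""


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizedAxiomSet:
    """Axioms in EL normal form.

    ``atomic``     -- pairs (A, B) for A ⊑ B
    ``conjunctions`` -- pairs (frozenset of names, B) for A1 ⊓ … ⊓ An ⊑ B
    ``exist_right``  -- triples (A, r, B) for A ⊑ ∃r.B
    ``exist_left``   -- triples (r, A, B) for ∃r.A ⊑ B

    All of A, B are named classes, possibly fresh.
    """

    atomic: set = field(default_factory=set)
    conjunctions: set = field(default_factory=set)
    exist_right: set = field(default_factory=set)
    exist_left: set = field(default_factory=set)
    fresh: set = field(default_factory=set)

    def names(self) -> set:
        out = set()
        for a, b in self.atomic:
            out |= {a, b}
        for cs, b in self.conjunctions:
            out |= set(cs) | {b}
        for a, _r, b in self.exist_right:
            out |= {a, b}
        for _r, a, b in self.exist_left:
            out |= {a, b}
        return out

    def rule_count(self) -> int:
        return (
            len(self.atomic)
            + len(self.conjunctions)
            + len(self.exist_right)
            + len(self.exist_left)
        )


def _check_el(expr) -> None:
    if isinstance(expr, Named):
        return
    if isinstance(expr, Existential):
        _check_el(expr.filler)
        return
    if isinstance(expr, Conjunction):
        for op in expr.operands:
            _check_el(op)
        return
    raise NonELConstructError(
        f"non-EL construct {type(expr).__name__!r} encountered"
    )


def normalize(ont: Ontology) -> NormalizedAxiomSet:
    """Rewrite the ontology's class axioms into EL normal form.

    Entailment-preserving over the original names; fresh names are a pure
    function of the subexpression they stand for, so repeated normalization
    of the same ontology yields the identical rule set.
    """
    out = NormalizedAxiomSet()

    def name_for(expr) -> str:
        if isinstance(expr, Named):
            return expr.concept
        n = fresh_name(expr)
        out.fresh.add(n)
        return n

    def flatten_conjuncts(expr) -> set:
        ops = set()
        for op in expr.operands:
            if isinstance(op, Conjunction):
                ops |= flatten_conjuncts(op)
            else:
                ops.add(op)
        return ops

    def norm(left, right) -> None:
        _check_el(left)
        _check_el(right)
        # Right side first: split conjunctions, name complex fillers.
        if isinstance(right, Conjunction):
            for op in flatten_conjuncts(right):
                norm(left, op)
            return
        if isinstance(right, Existential) and not isinstance(right.filler, Named):
            n = name_for(right.filler)
            norm(left, Existential(right.role, Named(n)))
            norm(Named(n), right.filler)
            return
        if isinstance(right, Existential) and not isinstance(left, Named):
            n = name_for(left)
            norm(left, Named(n))
            norm(Named(n), right)
            return
        # Right side is now named (or ∃r.Named with named left).
        if isinstance(left, Conjunction):
            ops = flatten_conjuncts(left)
            names = []
            for op in sorted(ops, key=canonical):
                if isinstance(op, Named):
                    names.append(op.concept)
                else:
                    n = name_for(op)
                    norm(op, Named(n))
                    names.append(n)
            if len(names) == 1:
                norm(Named(names[0]), right)
            else:
                out.conjunctions.add((frozenset(names), name_for(right)))
            return
        if isinstance(left, Existential):
            if not isinstance(left.filler, Named):
                n = name_for(left.filler)
                norm(left.filler, Named(n))
                norm(Existential(left.role, Named(n)), right)
                return
            out.exist_left.add((left.role, left.filler.concept, name_for(right)))
            return
        # left is named
        if isinstance(right, Named):
            if left != right:
                out.atomic.add((left.concept, right.concept))
            return
        # right is ∃r.Named
        out.exist_right.add((left.concept, right.role, right.filler.concept))

    for ax in ont.axioms:
        if ax.kind is AxiomKind.EQUIVALENT:
            norm(ax.left, ax.right)
            norm(ax.right, ax.left)
        else:
            norm(ax.left, ax.right)
    return out


# ---------------------------------------------------------------------------
# Saturation
# ---------------------------------------------------------------------------

def _super_roles(roles: dict) -> dict:
    """Reflexive-transitive closure of the role hierarchy."""
    closure = {}
    for rid in roles:
        supers = set()
        cur = rid
        while cur is not None and cur not in supers:
            supers.add(cur)
            parent = roles.get(cur)
            cur = parent.parent if parent is not None else None
        closure[rid] = supers
    return closure


def _compiled_chains(roles: dict, chains) -> list:
    """Explicit chains plus ``r ∘ r ⊑ r`` for every transitive role."""
    out = list(chains)
    for rid, role in roles.items():
        if role.transitive:
            rc = RoleChain((rid, rid), rid)
            if rc not in out:
                out.append(rc)
    return out


def saturate(n: NormalizedAxiomSet, roles: dict, chains=()) -> dict:
    """Least fixpoint of the EL completion rules.

    Returns the map ``S``: concept id -> set of entailed named superclasses
    (reflexive, and including fresh names).  ``roles`` maps role id ->
    :class:`~seponto.core_model.Role`; ``chains`` is an iterable of
    :class:`~seponto.core_model.RoleChain`.
    """
    supers_of = _super_roles(roles)
    all_chains = _compiled_chains(roles, chains)
    chain_by_first: dict = {}
    chain_by_second: dict = {}
    for ch in all_chains:
        chain_by_first.setdefault(ch.lhs[0], []).append((ch.lhs[1], ch.rhs))
        chain_by_second.setdefault(ch.lhs[1], []).append((ch.lhs[0], ch.rhs))

    atomic_idx: dict = {}
    for a, b in n.atomic:
        atomic_idx.setdefault(a, []).append(b)
    conj_idx: dict = {}
    for cs, b in n.conjunctions:
        for member in cs:
            conj_idx.setdefault(member, []).append((cs, b))
    exist_r_idx: dict = {}
    for a, r, b in n.exist_right:
        exist_r_idx.setdefault(a, []).append((r, b))
    exist_l_idx: dict = {}
    for r, a, b in n.exist_left:
        exist_l_idx.setdefault((r, a), []).append(b)

    names = n.names()
    S: dict = {a: {a} for a in names}
    edges: dict = {}          # role -> set of (src, tgt)
    out_edges: dict = {}      # src -> set of (role, tgt)
    in_edges: dict = {}       # tgt -> set of (role, src)
    todo: deque = deque()

    def add_sub(a: str, b: str) -> None:
        bucket = S.setdefault(a, {a})
        if b not in bucket:
            bucket.add(b)
            todo.append(("s", a, b))

    def add_edge(role: str, src: str, tgt: str) -> None:
        for s in supers_of.get(role, {role}):
            es = edges.setdefault(s, set())
            if (src, tgt) not in es:
                es.add((src, tgt))
                out_edges.setdefault(src, set()).add((s, tgt))
                in_edges.setdefault(tgt, set()).add((s, src))
                todo.append(("e", s, src, tgt))

    for a in list(names):
        todo.append(("s", a, a))

    while todo:
        item = todo.popleft()
        if item[0] == "s":
            _, a, b = item
            for c in atomic_idx.get(b, ()):
                add_sub(a, c)
            for cs, c in conj_idx.get(b, ()):
                if cs <= S[a]:
                    add_sub(a, c)
            for r, b2 in exist_r_idx.get(b, ()):
                add_edge(r, a, b2)
            for r, src in in_edges.get(a, set()).copy():
                for c in exist_l_idx.get((r, b), ()):
                    add_sub(src, c)
        else:
            _, r, src, tgt = item
            for b in S.get(tgt, {tgt}).copy():
                for c in exist_l_idx.get((r, b), ()):
                    add_sub(src, c)
            for r2, s in chain_by_first.get(r, ()):
                for rr, t2 in out_edges.get(tgt, set()).copy():
                    if rr == r2:
                        add_edge(s, src, t2)
            for r1, s in chain_by_second.get(r, ()):
                for rr, s2 in in_edges.get(src, set()).copy():
                    if rr == r1:
                        add_edge(s, s2, tgt)
    return S


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Taxonomy:
    """A classified ontology.

    ``closure`` is the full reflexive-transitive subsumption relation over
    declared (non-fresh) concepts; ``direct`` maps each equivalence-class
    representative to its sorted tuple of direct parent representatives
    (the transitive reduction); ``equivalence_classes`` lists every group of
    mutually subsuming concepts as a sorted tuple, keyed by its
    lexicographically least member.
    """

    closure: frozenset
    direct: dict
    equivalence_classes: tuple
    representative: dict

    def contains(self, sub: str, super_: str) -> bool:
        return sub == super_ or (sub, super_) in self.closure

    def ancestors(self, cid: str) -> list:
        return sorted(b for a, b in self.closure if a == cid and b != cid)

    def descendants(self, cid: str) -> list:
        return sorted(a for a, b in self.closure if b == cid and a != cid)

    def direct_parents(self, cid: str) -> tuple:
        return self.direct.get(self.representative[cid], ())

    def concepts(self) -> list:
        return sorted(self.representative)

    def reclosed(self) -> frozenset:
        """Transitive closure rebuilt from ``direct`` and the equivalences.

        Used to check (and test) that the direct-parent map is a faithful
        reduction of ``closure``.
        """
        g = nx.DiGraph()
        g.add_nodes_from(self.direct)
        for rep, parents in self.direct.items():
            for p in parents:
                g.add_edge(rep, p)
        reach = {rep: nx.descendants(g, rep) | {rep} for rep in g.nodes}
        members: dict = {}
        for group in self.equivalence_classes:
            rep = min(group)
            members[rep] = group
        pairs = set()
        for rep, reps_above in reach.items():
            for sub in members[rep]:
                for rep2 in reps_above:
                    for sup in members[rep2]:
                        pairs.add((sub, sup))
        return frozenset(pairs)


def classify(ont: Ontology, *, precomputed: dict = None) -> Taxonomy:
    """Classify *ont* into a :class:`Taxonomy`.

    Fresh normalization names are excluded from every output; all orderings
    are lexicographic, so classification is deterministic.
    """
    if precomputed is None:
        S = saturate(normalize(ont), ont.roles, ont.chains)
    else:
        S = precomputed
    declared = set(ont.concepts)
    closure = set()
    for a in declared:
        for b in S.get(a, {a}):
            if b in declared:
                closure.add((a, b))

    # group mutually subsuming concepts
    pair_set = closure
    groups: dict = {}
    for a in declared:
        eq = tuple(sorted(
            b for b in declared
            if (a, b) in pair_set and (b, a) in pair_set
        ))
        groups[a] = eq
    representative = {a: groups[a][0] for a in declared}
    eq_classes = tuple(sorted(set(groups.values())))

    reps = sorted(set(representative.values()))
    g = nx.DiGraph()
    g.add_nodes_from(reps)
    for a, b in pair_set:
        ra, rb = representative[a], representative[b]
        if ra != rb:
            g.add_edge(ra, rb)
    reduced = nx.transitive_reduction(g)
    direct = {rep: tuple(sorted(reduced.successors(rep))) for rep in reps}

    return Taxonomy(
        closure=frozenset(closure),
        direct=direct,
        equivalence_classes=eq_classes,
        representative=representative,
    )


def entails(ont: Ontology, sub: str, super_: str, taxonomy: Taxonomy = None) -> bool:
    """True iff *sub* ⊑ *super_* follows from the ontology.

    Pass a precomputed *taxonomy* to avoid re-classifying on every query.
    """
    if sub not in ont.concepts:
        raise UnknownIdError(f"unknown concept {sub!r}")
    if super_ not in ont.concepts:
        raise UnknownIdError(f"unknown concept {super_!r}")
    if taxonomy is None:
        taxonomy = classify(ont)
    return taxonomy.contains(sub, super_)
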