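"""Classification impact diffing: the iterative QA loop.

Editing a partonomy can silently re-place every dependent concept modelled
with the edited anatomy.  The QA loop therefore classifies the ontology
before and after an edit and reports every subsumption pair gained and lost
in the dependent hierarchies, so reviewers can spot incorrect new placements
and inadvertently lost relationships.

Diffs are computed on full subsumption closures, not on direct-parent maps:
direct parents churn under transitive reduction even when no entailment
changed, while closure diffs say exactly which relationships appeared or
disappeared.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core_model import Ontology, SemanticClass
from .el_reasoner import Taxonomy, is_fresh


@dataclass(frozen=True)
class ImpactDiff:
    """Gained and lost subsumption pairs between two classifications."""

    gained: frozenset
    lost: frozenset
    filters: tuple = ()

    def is_empty(self) -> bool:
        return not self.gained and not self.lost


def _reflexive_stripped(closure) -> set:
    return {(a, b) for a, b in closure if a != b}


def diff_taxonomies(
    before: Taxonomy,
    after: Taxonomy,
    *,
    ontology: Ontology = None,
    filter_classes=None,
) -> ImpactDiff:
    """Closure difference between two classified taxonomies.

    ``filter_classes`` optionally restricts the reported pairs to those whose
    *sub* concept belongs to one of the given semantic classes (e.g.
    disorders only); it requires *ontology* for the concept metadata.
    Reflexive pairs never count as changes; fresh normalization names never
    appear (classify already excludes them, and this is re-enforced here).
    """
    gained = _reflexive_stripped(after.closure) - _reflexive_stripped(before.closure)
    lost = _reflexive_stripped(before.closure) - _reflexive_stripped(after.closure)
    gained = {(a, b) for a, b in gained if not (is_fresh(a) or is_fresh(b))}
    lost = {(a, b) for a, b in lost if not (is_fresh(a) or is_fresh(b))}
    filters: tuple = ()
    if filter_classes:
        if ontology is None:
            raise ValueError("filter_classes requires the ontology for metadata")
        wanted = {SemanticClass(f) for f in filter_classes}
        filters = tuple(sorted(f.value for f in wanted))

        def keep(pair):
            c = ontology.concepts.get(pair[0])
            return c is not None and c.semantic_class in wanted

        gained = set(filter(keep, gained))
        lost = set(filter(keep, lost))
    return ImpactDiff(frozenset(gained), frozenset(lost), filters)


def _fsn(ontology: Ontology, cid: str) -> str:
    if ontology is not None and cid in ontology.concepts:
        return ontology.concepts[cid].fsn
    return cid


def impact_report(
    diff: ImpactDiff,
    *,
    ontology: Ontology = None,
    curated=(),
) -> str:
    """Human-readable, stably ordered listing of an impact diff.

    If curated entailments are supplied, any changed pair that matches one is
    annotated; a *gained* pair matching a curated negative (a subsumption the
    model must not produce) is flagged as a containment-law violation, and a
    *lost* pair matching a curated positive as a lost required relationship.
    """
    by_pair = {(e.sub, e.super): e for e in curated}
    lines = []
    if diff.filters:
        lines.append("filter: " + ", ".join(diff.filters))
    if diff.is_empty():
        lines.append("no classification changes")
        return "\n".join(lines)
    for heading, pairs in (("gained", diff.gained), ("lost", diff.lost)):
        if not pairs:
            continue
        lines.append(f"{heading} ({len(pairs)}):")
        for sub, sup in sorted(pairs):
            line = f"  {_fsn(ontology, sub)} -> {_fsn(ontology, sup)}"
            entry = by_pair.get((sub, sup))
            if entry is not None:
                if heading == "gained" and not entry.expected:
                    line += f"  [VIOLATES containment law: {entry.source}]"
                elif heading == "lost" and entry.expected:
                    line += f"  [LOST required relationship: {entry.source}]"
            lines.append(line)
    return "\n".join(lines)


def impact_table(diff: ImpactDiff) -> str:
    """Machine-readable tab-delimited report (change, sub, super)."""
    rows = ["change\tsub\tsuper"]
    for sub, sup in sorted(diff.gained):
        rows.append(f"gained\t{sub}\t{sup}")
    for sub, sup in sorted(diff.lost):
        rows.append(f"lost\t{sub}\t{sup}")
    return "\n".join(rows) + "\n"
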