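# Methods

## The modelling problem

Regional anatomical terms — above all "abdomen" — are polysemous: the same
word names the abdominopelvic cavity, that cavity minus the true pelvis, the
cavity-plus-contents ("intra-") aggregate, the same with the anterior
abdominal wall, the full-thickness radiological cross-section, and more.
When disorders and procedures are *defined* over anatomy and a classifier
derives their hierarchy, any ambiguity in the anatomy propagates into wrong
clinical inferences. The package encodes the disambiguated model of the
trunk as a formal EL ontology in which every such reading is a distinct,
logically placed concept, so that each asserted or denied subsumption is
machine-checkable.

## The SEP pattern and the role box

Every anatomical entity *X* is modelled by three classes:

```
Structure of X ≡ ∃ all-or-part-of . Entire X
X part        ≡ ∃ proper-part-of . Entire X
Entire X ⊑ Structure of X          (the "all of" reading)
X part   ⊑ Structure of X
```

The "all of" reading of `all-or-part-of` is carried by the explicit axiom
`Entire X ⊑ Structure of X` rather than by a reflexive role: on the
ontologies in scope the entailments are identical, and the rule engine stays
free of reflexivity handling.

The role box is:

| role                     | parent          | transitive |
|--------------------------|-----------------|-----------|
| all-or-part-of           | —               | yes |
| proper-part-of           | all-or-part-of  | yes |
| regional-part-of         | proper-part-of  | no |
| constitutional-part-of   | proper-part-of  | no |
| systemic-part-of         | proper-part-of  | no |
| finding-site             | —               | no |
| procedure-site           | —               | no |

plus one complex role inclusion beyond the transitivity chains:

```
all-or-part-of ∘ proper-part-of ⊑ proper-part-of
```

Transitivity alone (`r ∘ r ⊑ r`) propagates `Structure(child) ⊑
Structure(parent)` along part chains, but not `Structure(child) ⊑
Part(parent)`; the extra chain — anything that is all or part of a proper
part is itself a proper part — supplies exactly that entailment (e.g.
`Structure of lobe of liver ⊑ Liver part`) and is valid meronymy. It is
regular (the right-hand role ends its own left-hand side), so polynomial
classification is preserved.

A second pattern covers body cavities. `Intra-X structure` is the primitive
aggregation of `Structure of X cavity` and `Content of X cavity` — the
space-and-contents reading of "intra-". The walls that delineate a cavity
are deliberately *not* under the intra- concept; they are parts of the
enclosing segment.

Dependent concepts are fully defined with a single existential:
`Disorder of X ≡ Disorder ⊓ ∃ finding-site . Structure of X` (procedures use
`procedure-site`). No role groups are used; none of the modelled entailments
need them. Two dependents defined on the same site are mutually equivalent
by construction, which the taxonomy represents as an equivalence class.

## The reasoner

Classification follows the standard polynomial EL procedure:

1. **Normalization.** Equivalences are split into two inclusions; axioms are
   rewritten into the four normal forms `A ⊑ B`, `A1 ⊓ … ⊓ An ⊑ B`,
   `A ⊑ ∃r.B`, `∃r.A ⊑ B` over named classes. Fresh names are a pure
   function (`"N-" + sha1` of the canonical form) of the subexpression they
   replace, so normalization is deterministic and repeatable; the same
   subexpression reused on both polarities reuses one name, which is sound
   (the name becomes equivalent to the expression).
2. **Saturation.** A worklist computes the least fixpoint of the completion
   rules: atomic inclusion, conjunction, existential introduction,
   existential on the left, role hierarchy (edges are added to all
   super-roles eagerly) and binary role chains (transitivity is compiled to
   `r ∘ r ⊑ r`). No goal-directed optimisation is attempted — full
   saturation is instantaneous at the scales in scope (the trunk fixture has
   163 concepts and classifies in ~30 ms).
3. **Taxonomy.** The closure restricted to declared (non-fresh) concepts is
   grouped into equivalence classes (mutual subsumption; the representative
   is the lexicographically least id, a deterministic tie-break chosen for
   diff stability), and the strict order on representatives is transitively
   reduced (networkx) into the direct-parent map. Re-closing the
   direct-parent map reproduces the closure exactly; this algebraic
   round-trip is tested.

## The independent oracle

`synthetic.naive_closure` decides subsumption by a genuinely different
algorithm: it builds the canonical model of the ontology with a chase — one
element per named concept plus one per existential filler expression, labels
and role edges grown by unindexed fixpoint iteration over the original,
un-normalized axioms, with role-hierarchy lifting and chain composition
applied to edges. `A ⊑ B` holds iff the element introduced for `A` satisfies
`B` in the final model. The oracle shares no code with the completion-rule
reasoner and is kept simple rather than fast; a size guard (default 15
concepts) protects property tests from accidental blow-up and must be
raised explicitly for larger closures (the impact-QA cross-check does so for
the trunk fixture, where one chase takes ~0.1 s).

The central correctness evidence is pair-for-pair agreement of the two
closures on 1000 seeded random EL ontologies (≤ 12 concepts, ≤ 3 roles,
existential probability 0.4, conjunction probability 0.3, expression depth
≤ 2, half the roles transitive) — conditions chosen to exercise every
completion rule, including nested fillers and random role hierarchies. The
generator's RBoxes contain hierarchies and transitivity only; two-role
chains are exercised by the trunk fixture and dedicated reasoner tests.

## The trunk fixture

Concepts carry released SNOMED CT identifiers verbatim where published
(Table-2 and figure-caption SCTIDs: the four cavities, three segments, three
cross-sections, three clinical regions, the posterior wall of abdomen
proper, and the trunk root); everything else lives in the reserved local
`X-` namespace. Fully specified names keep their semantic-tag suffix.

Modelling choices where the published account leaves the encoding open:

* **"And/or" aggregations.** EL has no disjunction, so the combined pelvic
  cavity and the three clinical regions ("Abdomen", "Abdomen proper",
  "Pelvic region") are primitive concepts with each disjunct asserted into
  them by a SubClassOf axiom, and with asserted placements into their
  enclosing volumes. This reproduces every asserted subsumption; what is
  lost is only the converse inference (that the aggregate is *nothing but*
  the disjuncts), which no modelled entailment needs.
* **"Entire abdomen proper" as a part-whole parent.** The liver's
  constitutional-part placement targets the abdomen proper *segment of
  trunk* entity; this yields the classical chain liver structure ⊑ abdominal
  proper structure ⊑ abdominopelvic structure, and the matching disorder
  chain, without inventing a second "abdomen proper" entity.
* **Non-disjoint volumes.** The abdomen proper and pelvic segments share the
  false pelvis: the false-pelvis cavity is asserted into both. The thoracic
  and abdominal cross-sections share the T8/T9–T12/L1 band, modelled as a
  shared sub-volume asserted as a regional part of both. No disjointness is
  stated anywhere (EL has none; nothing is lost since the tests check
  non-entailment, not inconsistency).
* **Iliac colon.** Its membership in the pelvic segment is carried by one
  explicit regional-part axiom (plus a content assertion into the false
  pelvis); the false-pelvis *content* class is deliberately not asserted
  wholesale into the pelvic segment or pelvic region. This keeps "which
  false-pelvis contents count as clinically pelvic" a per-concept editorial
  decision — exactly the judgement the impact-QA loop is meant to audit, and
  the removal of that single axiom is the first scripted edit scenario.
* **Perineum and external genitalia** are constitutional parts of the pelvic
  segment but not of the pelvic region (which is bounded by and includes the
  pelvic diaphragm). No axiom links the external genitalia to the pelvic
  cross-section: that boundary is inherently fuzzy ("part but not
  necessarily the entire external genitalia"), so the model stays silent and
  the curated suite records the non-entailment.
* **Gendered contents** of the true pelvis are both loaded by default as
  plain content concepts; no sex axioms are stated, and the placement of the
  six shared contents is invariant under which gendered set is loaded
  (tested over all four load combinations).
* **Gravid uterus.** The uterus is asserted into the true-pelvis contents
  (native state). Physiological change — the gravid uterus expanding into
  the abdomen proper — is documented, not modelled; the clinical "Abdomen"
  contains the uterus in either state, which is the mitigation the model
  relies on.

The curated suites (24 positive, 15 negative entries, each with a source
citation) are the executable statement of the containment law over this
fixture; a separate structural test checks that classified
structure-to-structure subsumption coincides exactly with reachability in
the asserted placement graph.

## Impact QA

Diffs are computed on full closures, not direct-parent maps: transitive
reduction churns direct parents even when no entailment changed, whereas
closure diffs are precisely the gained and lost relationships. Reflexive
pairs and fresh normalization names are excluded; an optional semantic-class
filter restricts reports to a dependent hierarchy (e.g. disorders). The text
report cross-references the curated suites: a gained pair matching a curated
negative is flagged as a containment-law violation, a lost pair matching a
curated positive as a lost required relationship. EL monotonicity guarantees
that any single added axiom has an empty lost set — tested, and useful as a
sanity check on review tooling.

## Release formats

The RF2-style dialect is three UTF-8, tab-delimited, LF files with header
rows (`concepts.tsv`: id, primitive, semanticClass; `descriptions.tsv`:
conceptId, term, type ∈ {FSN, preferred, synonym}; `axioms.tsv`: one
functional-syntax axiom per row, including the role box). It intentionally
omits effectiveTime/moduleId/active — release management is out of scope —
and is therefore non-conformant but mechanically convertible. Serialized
axioms reuse the OWL functional-syntax subset so there is exactly one
expression grammar. Both writers sort all rows (conjunction operands by
canonical form), making output byte-stable; both readers report errors with
file and line, ignore unknown columns with a warning, and reject any OWL
construct outside the EL subset by name. The shipped golden files are the
trunk RF2 bundle and the liver-exemplar functional-syntax document;
byte-stability of the full trunk functional-syntax serialization is checked
by double-write comparison.

## Limitations

* No disjointness, negation, disjunction, universal restriction, nominals or
  concrete domains — the EL fragment only. "Mutually exclusive" anatomy can
  be tested as non-entailment but not asserted as inconsistency.
* The trunk fixture is a faithful but *partial* anatomy: exemplar organs and
  contents sufficient to exercise every published inference, not the full
  SNOMED anatomy branch (no surface-region grid, no vasculature beyond the
  aorta exemplar).
* Dependents propagate only through the structure hierarchy (one existential
  per definition, no role groups, no part-of-over-finding-site chain).
* The synthetic generator emulates structural variety (random hierarchies,
  conjunctions, nested existentials), not the statistical shape of real
  terminologies; oracle agreement on it demonstrates calculus correctness,
  not coverage of editorial-scale ontologies.
* Full saturation without goal-direction is quadratic-to-cubic in practice;
  fine below ~10³ concepts, not intended for million-concept releases.
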