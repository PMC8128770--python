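# seponto

**SEP-model meronymic reasoning over EL ontologies, with an executable
regional anatomy of the human trunk.**

Clinical terminologies such as SNOMED CT must answer questions like *is a
disorder of the liver a disorder of the abdomen?* by machine reasoning, not
by convention. That requires part–whole (meronymic) knowledge expressed so
that a description-logic classifier can propagate it: the SEP pattern gives
every anatomical entity three classes — `Entire X` (whole entities),
`X part` (proper parts) and `Structure of X ≡ ∃ all-or-part-of. Entire X`
(the whole and/or any part) — and placement axioms such as
`Entire liver ⊑ ∃ constitutional-part-of. Entire abdomen proper` then make
the structure hierarchy mirror the partonomy after classification. The
*containment law* governs the modelling: a structure may be classified under
another structure only when the entity lies entirely within the superordinate
boundary (the arch of the aorta is intra-thoracic; the aorta is not).

`seponto` is a compact toolkit for building, classifying and quality-assuring
such ontologies, for terminology engineers and ontologists:

* **core_model** — concepts, roles (hierarchy, transitivity, chains), EL
  class expressions (names, conjunction, existential) and axioms;
* **sep_builder** — the SEP triplet, cavity/content/"intra-" and
  site-defined dependent (disorder/procedure) axiom patterns;
* **el_reasoner** — a polynomial EL classifier: normalization into the four
  EL normal forms, completion-rule saturation with role hierarchies and role
  chains, and transitive reduction into a direct-parent taxonomy;
* **trunk_model** — an executable transcription of the published regional
  anatomy of the trunk (cavities, segments, radiological cross-sections,
  walls, the three clinical "abdomen" variants, exemplar contents and
  dependents), with curated positive/negative entailment suites;
* **impact_qa** — the iterative QA loop: classify before/after an edit and
  report every gained and lost subsumption in dependent hierarchies;
* **io_formats** — a simplified tab-delimited RF2-style release dialect, an
  OWL 2 functional-syntax subset, and the `seponto` CLI;
* **synthetic** — a seeded random EL ontology generator and an independent
  canonical-model oracle used to witness the reasoner's correctness.

## Worked example

```python
from seponto import classify, entails
from seponto.trunk_model import build_trunk_model, ABDOMEN_REGION

trunk = build_trunk_model()
taxonomy = classify(trunk.ontology)

liver = trunk.triplets["liver"].structure            # 'Liver structure'
print(taxonomy.contains(liver, "818985005"))         # abdomen proper segment
print(taxonomy.contains(liver, ABDOMEN_REGION))      # clinical 'Abdomen'
print(taxonomy.contains(trunk.triplets["anal canal"].structure,
                        "X-intra-abdominopelvic"))
print(taxonomy.ancestors("X-disorder-of-liver"))
```

prints

```
True
True
False
['X-disorder', 'X-disorder-of-abdomen-proper', 'X-disorder-of-abdominopelvic-segment']
```

— the liver structure is classified into the abdomen proper segment and the
clinical "Abdomen", the anal canal (which crosses the pelvic diaphragm) is
*not* an intra-abdominopelvic structure, and a disorder of the liver is
automatically a disorder of the abdomen proper and of the abdominopelvic
segment of trunk.

The same checks from the shell:

```sh
seponto build-trunk --out trunk/            # three-table RF2-style bundle
seponto entails trunk X-liver-s 818983003   # exit 0: liver is in 'Abdomen'
seponto classify trunk --out taxonomy.tsv   # direct-parent pairs
seponto diff trunk edited/ --filter disorder
seponto export trunk --to ofn trunk.ofn
```

## Documentation

`docs/methods.md` describes the model, the reasoning calculus, the role box,
the numerical/design choices and the known limitations.
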