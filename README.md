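# plgrouper

Organize electronic health record (EHR) problem lists by clinical system,
and measure how well the organization matches clinician judgment.

## The problem

A problem list (PL) is the EHR's running repository of a patient's diagnoses.
Left alphabetized, a long PL scatters related diagnoses (a lung nodule, the
lung cancer it became, and the metastases) across the page. A clinically
useful alternative is to section the list by specialty/system — but ICD-10-CM,
the coding system PL entries carry, is a flat billing classification and does
not support that grouping well. SNOMED CT does: it is a polyhierarchic
ontology in which a concept may have several parents and a high-level concept
*subsumes* all of its transitive descendants, so a handful of parent concepts
can stand in for thousands of specific diagnoses.

`plgrouper` implements that approach end to end:

* **Subsumption groupers with Boolean exclusion.** A grouper *G* is a named,
  ranked pair of concept-root sets over an is-a DAG, with member set

  ```
  members(G) = ⋃ᵢ desc-or-self(iᵢ)  \  ⋃ₑ desc-or-self(eₑ)
  ```

  for include roots *iᵢ* and exclude roots *eₑ*. Exclusion always dominates,
  even when the polyhierarchy reaches a concept from both sides — this is
  what lets a Dermatology grouper carve skin cancers out of an Oncology
  grouper defined at the malignant-neoplasm root.
* **Priority classification with an "Other" fallback.** Each PL entry is
  mapped ICD-10-CM → concept via a user-supplied mapping table, then assigned
  to the lowest-ranked grouper whose member test passes; concepts matched by
  no grouper (too general to attribute) and unmapped codes fall to the
  "Other" section, always last (rank 22).
* **Evaluation machinery.** Dual-reviewer TP/FP/TN/FN categorization
  (TP = right system, FP = wrong system, TN = correctly "Other",
  FN = wrongly "Other"), third-rater adjudication, raw agreement, unweighted
  Cohen κ, and confusion metrics (sensitivity = tp/(tp+fn), specificity =
  tn/(tn+fp), PPV, NPV, F1 = 2tp/(2tp+fp+fn)), rendered half-away-from-zero
  in exact rational arithmetic. A reconstruction utility inverts printed
  (rounded) study marginals back to the integer confusion matrix by
  exhaustive search.
* **Synthetic fixtures.** A seeded generator for labeled toy ontologies,
  grouper definitions, mappings and problem lists with gold labels, so the
  whole pipeline is testable without any terminology license or download.

## Worked example

```python
import plgrouper as pg

toy = pg.toy_fixture_dir()
onto = pg.load_ontology(toy / "ontology_edges.tsv", dialect="edge_list")
groupers = pg.compile_groupers(pg.load_grouper_definitions(toy / "groupers.yaml"), onto)
grouped = pg.organize_problem_list(
    pg.read_problem_list(toy / "problems.csv"),
    pg.load_mapping(toy / "mapping.tsv"),
    groupers, onto,
)
```

Running `python examples/01_organize_toy_problem_list.py` prints:

```
[ 2] Oncology
      C34.90   Lung cancer (multi-system)
[ 3] Cardiovascular and Peripheral Vascular
      I48.91   Atrial fibrillation
[ 4] Respiratory and Allergy
      R91.1    Lung nodule
      J45.909  Asthma
[ 8] Infectious Disease, Immune, or Lymphatic
      J18.9    Community-acquired pneumonia
[15] Dermatology
      C44.92   Squamous cell carcinoma of skin
[22] Other
      R60.9    Edema
      Z79.01   Anticoagulated
      Q99.9    Chromosomal abnormality unspecified
      X99.99   Legacy local code

entries: 10, unmapped: 2
```

Lung nodule sorts into Respiratory while lung cancer — a member of both the
Oncology and Respiratory member sets — takes the lower rank, Oncology.
Squamous cell carcinoma of skin descends from the Oncology include root but
is excluded there and is captured by Dermatology. Edema is a finding too
general to attribute and stays in "Other", along with two codes absent from
the mapping table (`unmapped: 2`).

The other scripts in `examples/` show confusion-matrix reconstruction from
printed marginals (`02`), the dual-review/κ workflow (`03`), and a full
synthetic study with gold-label scoring (`04`). A thin CLI wraps the same
functions for file-level runs: `plgrouper organize|evaluate|validate|simulate
-c config.yaml`.

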