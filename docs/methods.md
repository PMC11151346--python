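# Methods

## The grouping model

`plgrouper` treats a clinical terminology as a directed acyclic is-a
polyhierarchy: concepts are nodes, each concept may have several parents, and
concept *A* subsumes *B* when *B* is *A* or a transitive descendant. Only the
is-a skeleton is modeled — description-logic roles, refsets and release
management are out of scope, because the grouping method uses nothing else.
Inactive concepts are retained for audit but excluded from traversal; a
diagnosis mapped onto an inactive concept is treated as unmapped. Multiple
roots (a forest) are permitted; a single shared root is the common case.

A **grouper** is a named, ranked definition `(include_roots, exclude_roots)`.
Its member set is the descendant-or-self closure of the include roots minus
the descendant-or-self closure of the exclude roots. Exclusion dominates
inclusion unconditionally: a concept reachable from an include root through
one parent chain and from an exclude root through another is *not* a member.
This is deliberate — the carve-out pattern (skin cancers excluded from an
Oncology grouper rooted at malignant neoplasm, and captured instead by a
Dermatology grouper) only works under exclusion-wins semantics in a
polyhierarchy.

**Classification** walks the groupers in ascending rank and assigns a concept
to the first whose member test passes. The rank order is fixed by the
definition file (21 system/condition groupers in presentation order; "Other"
is implicit at rank 22 and always last). Nothing in the underlying clinical
workflow dictates what happens when a concept satisfies several groupers, so
the package makes the deterministic choice: lowest rank wins, and every match
is recorded in a `match_trace` with a `multi_match` flag for audit. Permuting
the input order of a grouper list cannot change any assignment.

**Problem-list organization** maps each entry's ICD-10-CM code to concepts
through a user-supplied table (vendor mappings are licensed content; the
package only defines the format), classifies, and emits ranked sections.
Two mapping policies exist because production terminology servers differ on
the point: `primary_only` (default) classifies on the code's single primary
concept; `all` classifies on every mapped concept and takes the best (lowest)
rank. Within a section, entries sort by `noted_date` descending then
case-insensitive display text (`date_then_alpha`, default — recent problems
first is the clinically useful open substitute for proprietary display
orders), or alphabetically (`alpha`). Both knobs are explicit configuration.

## Evaluation framework

Reviewed items are categorized TP (right system), FP (wrong system), TN
(correctly left in "Other": the mapped concept genuinely is too unspecific),
FN (wrongly left in "Other": a grouper logic deficit). Two raters categorize
independently; items they come to agree on after discussion are modeled as
revised rater columns, and only genuine third-rater tie-breaks count as
adjudications — the two-stage distinction matters when reporting an
adjudication tally.

Metrics follow the standard formulas (sensitivity tp/(tp+fn), specificity
tn/(tn+fp), PPV tp/(tp+fp), NPV tn/(tn+fn), F1 2tp/(2tp+fp+fn)). A zero
denominator yields an explicit undefined (`None`), never a silent 0. Cohen κ
is unweighted over the four assessment categories (the recording instrument
of the review), computed in exact rationals; κ over grouper attributions
rather than categories would need per-item attribution data and is not
implemented.

**Rendering.** Percentages print at one decimal and F1 at three, rounded
half-away-from-zero in exact `Fraction` arithmetic, so boundary cases
(342/24 = 14.25 → 14.3) never depend on binary floating point or banker's
rounding. One documented anomaly in the source literature: an agreement of
821/869 was printed as 94.4% although the value rounds to 94.5%; the package
reports full precision plus the half-away rendering and does not emulate the
truncation.

**Reconstruction.** `reconstruct_counts(n_total, tn, sensitivity_pct,
ppv_pct)` searches all integer `(tp, fp, fn)` with `tp+fp+fn = n_total − tn`
for matrices whose sensitivity and PPV round (half-away, one decimal) to the
stated percentages, using exact integer inequalities for the rounds-to test.
All solutions are returned with a uniqueness flag; no solution is a hard
error. For the study-scale marginals (N = 869, TN = 37, 97.6 / 96.8) the
solution is unique, and specificity, NPV and F1 then follow as independent
consequences.

## Synthetic data

The generator emulates the structure the method depends on, not clinical
content:

* a shared root, one labeled subtree per system, and a small pool (~5% of
  concepts) of over-general findings attached only to the root — the mass
  whose correct home is "Other";
* polyhierarchy: with probability `polyhierarchy_prob` (default 0.05) a new
  concept takes a second parent within its own system;
* *exclusion grafts*: per system, with probability `exclusion_graft_prob`
  (default 0.3), a subtree physically placed inside that system's hierarchy
  but truly owned by another system. Grafts attach only to genuine host
  territory (tracked physical system), never inside another foreign graft —
  nested grafts would let two systems' excludes annihilate a subtree that by
  construction belongs to one of them. Derived grouper definitions include a
  system's own graft roots and exclude foreign graft roots hosted inside it,
  so classification provably recovers the generative labels on noise-free
  data (a tested invariant);
* per-patient diagnosis counts from a discretized log-normal with median 12
  and σ = 0.86 (giving mean ≈ 17.4 > median, the right-skew of real PL
  burden), clamped to [4, 59]; 50 patients by default. Only the median and
  range are calibrated; the IQR is emergent;
* mapping noise: with probability `mapping_noise` (default 0.022) an entry's
  mapping row points at a strict ancestor of its true concept chosen among
  ancestors that belong to **no** grouper (the root always qualifies), so an
  over-generalized entry always surfaces as a false negative when its true
  concept was attributable. With probability `unmapped_prob` (default 0.01)
  the row is dropped entirely (gold "Other"). With probability
  `other_concept_prob` (default 0.033) the entry's true concept is drawn from
  the root pool (gold "Other"). The defaults reproduce the composition of a
  realistic review set: ≈ 4.3% gold-"Other" mass and ≈ 2% over-general
  mappings.

Gold labels are generative: an entry's gold grouper is its *true* concept's
system, "Other" for pool concepts and unmapped entries. Because
over-generalization always lands in "Other", the noise rate ε is an oracle
for the pipeline's FN+FP rate — the test suite checks the observed rate at
~10,000 entries against ε within three binomial standard errors.

What the generator does **not** emulate: clinical language, real ICD-10-CM
code semantics (fabricated codes only follow the letter+digits dotted
pattern), inter-reviewer disagreement processes, cross-system
over-generalization that would produce false positives, and duplicate or
conflicting entries. Passing tests therefore demonstrate correctness of the
subsumption/exclusion machinery and the evaluation arithmetic, not clinical
performance of any particular grouper content — the published ~1200-concept
production build is proprietary and is not reproduced here.

## Numerical and design choices

* Transitive queries delegate to graph reachability (networkx) per query;
  determinism and oracle equivalence (naive parent-expansion to fixpoint, and
  brute-force closure set-difference for compiled groupers) are the tested
  contracts, not any particular closure strategy.
* Ties in within-section ordering break on entry id last, so output is total
  and stable. Undated entries sort after dated ones.
* ICD-10-CM codes are canonicalized to upper-case dotted form (a dot inserted
  after position 3 for undotted input longer than 3). Malformed codes in a
  mapping file are skipped with a logged warning; two explicit primary rows
  for one code are a hard error; when no row is flagged primary the first row
  wins.
* Degenerate inputs are hard errors with named culprits: cyclic hierarchies
  (one on-cycle concept is reported), dangling parent references, unknown
  grouper roots (grouper and root named), discordant reviews without a
  tie-break, length-mismatched rater vectors.
* Problem sizes in the test suite (DAG oracles ≤ 200 nodes, calibration at
  ~10,000 entries from 600 patients, default studies at 50 patients) keep the
  full suite in the tens of seconds while leaving the binomial checks
  well-powered.

## Known limitations

* Grouper quality is entirely data-dependent: the package ships only a toy
  definition file; real deployments must author definitions against their
  terminology release.
* `policy="all"` takes the best rank across mapped concepts; a confidence- or
  frequency-weighted choice is out of scope.
* No duplicate merging, conflict resolution or PL cleanup — the organizer
  reorders, it never edits.
* κ is category-level; attribution-level κ would require per-item attribution
  pairs from both raters.
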