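# Methods

## Problem and model

A diagnostic labelling discrepancy is a substantial difference between the
diagnosis assigned at an index visit (here: emergency-department discharge)
and a later, more definitive diagnosis for the same complaint. Confirming a
discrepancy requires expert chart review; `icddx` implements the trigger
that makes review tractable: a distance between the two ICD-10 codes in the
coding hierarchy, with cases flagged for review when the distance crosses a
cutoff.

ICD-10 is modeled as a rooted tree with six fixed levels — virtual root
(depth 0), chapter (1), block (2), three-character category (3), four- and
five-character subcategories (4, 5). A node's depth always equals its level
rank, so depth, ancestor and lowest-common-ancestor (LCA) queries are O(depth)
pointer walks. The virtual root joins all chapters; without it, paths
between codes in different chapters would be undefined. The WHO print
edition additionally groups blocks within some chapters; we omit that level
for determinism, which caps the tree diameter at 10 (two depth-5 leaves in
different chapters).

For codes *a*, *b* with LCA depth *h* and path length
*l* = depth(*a*) + depth(*b*) − 2*h*, four algorithms are provided:

| name | formula | polarity | range |
|---|---|---|---|
| `steps` | *l* | distance | 0 … diameter |
| `weighted` | Σ edge weights along the path | distance | ≥ 0 |
| `wu_palmer` | 2*h* / (depth *a* + depth *b*) | similarity | [0, 1] |
| `li` | exp(−α*l*) · tanh(β*h*) | similarity | [0, 1] |

Edge weights are keyed by the deeper endpoint's level; the default penalizes
chapter transitions (root↔chapter edges weigh 2.0, all others 1.0), the
minimal scheme that makes cross-chapter moves costlier than within-chapter
moves. The Li constants default to α = 0.2, β = 0.6, the values proposed in
the original semantic-similarity literature for taxonomy trees; both the
weight map and (α, β) are configurable because the reference web tool does
not publish its internal settings. Wu–Palmer at the virtual root is defined
as 0 for distinct codes (h = 0) and 1 for root-vs-root; the root itself is
rejected as a diagnosis at the screening layer.

## Screening rules

* Flag when `value >= cutoff` for distances and `value <= cutoff` for
  similarities, so one validation code path serves all four algorithms
  after polarity mapping. The "≥" convention means a cutoff of 0 flags
  every scored pair, including identical codes.
* A patient with no documented follow-up care is assumed to have no change
  in diagnosis: the record is unscored and never flagged
  (`no_followup_assumed_unchanged`).
* When the follow-up letter lists several diagnoses, the effective
  follow-up is the one minimizing discrepancy against the index code
  (minimum distance / maximum similarity, ties to the first listed): a
  letter that still contains the ED diagnosis is not a relabeling.
* Unknown codes fail loudly by default; an explicit skip policy emits
  unscored `skipped_unknown_code` records, which are excluded from
  validation counts and reported in the run log.
* Chapter-R (symptom) codes are scored as ordinary nodes; no special-case
  rating rules are applied to them.
* Codes of unequal specificity are comparable (a category vs its own
  subcategory is 1 step), since index and follow-up diagnoses come at
  heterogeneous granularity.

## Validation

Validation consumes scored, expert-labeled records (a record is labeled
discrepant when its rating category is *diagnostically different* or
*hierarchically different*).

* **Cutoff sweep.** Confusion counts and sensitivity, specificity, FPR,
  FNR, PPV, NPV and Youden's J per cutoff, sorted by descending cutoff.
  Zero denominators yield missing values, rendered `-` in reports; report
  rounding is two decimals, internal computation full precision. The
  default grid is the set of distinct observed scores, extended by 0 and
  max + 1 for distance algorithms.
* **ROC/AUC.** The AUC is the tie-corrected concordance probability
  P(score_case > score_control) + ½ P(equal), computed from midranks, with
  similarity scores negated so larger always means more discrepant. The
  95% CI uses DeLong's asymptotic variance via midrank structural
  components (sample variances with ddof = 1), a symmetric normal interval
  on the untransformed AUC scale clipped to [0, 1]; with fewer than two
  observations in a class the variance contribution is taken as 0. The
  implementation reproduces R `pROC::ci.auc(method="delong")` to 1e-12 on
  a frozen test dataset.
* **Optimal cutpoints.** Maximum sensitivity, maximum specificity, and
  maximum Youden's J. Ties are broken by the complementary metric (among
  equally sensitive rows, highest specificity, and vice versa; Youden ties
  by higher specificity), then by the larger cutoff, which flags the
  fewest cases. The tie-break order is our choice; other conventions exist.
* **False-positive audit.** Flagged-but-non-discrepant records are
  decomposed by expert rating category. The *true NPV* is the share of
  false positives rated anything but *identical*: cases where the flag,
  though formally wrong against the discrepancy label, still points at a
  genuinely changed diagnosis (a refinement or a complication).

## Synthetic cohort

Real patient-level data for the validation study are not public, so the
generator reconstructs the cohort's *structure*: 1,204 pairs of which 932
are rated identical, 98 precision, 65 complication, 89 diagnostically
different and 12 hierarchically different (the five counts sum to 1,196;
the remaining 8 pairs carry no expert rating and are generated unlabeled),
with the 101 diagnostically/hierarchically different pairs constituting
the 8.4% discrepancy prevalence. Exact mode allocates all category and
sub-template counts deterministically by largest remainder (ties by
declaration order), so these marginals — and the degraded variant's 303
pairs without follow-up — are bit-reproducible at any seed; sampled mode
draws categories i.i.d. for distributional tests.

Each category maps to tree relationships (all configurable via
`CohortSpec.templates`); the defaults are chosen so that screening the
exact cohort at `steps >= 2` reproduces the validation study's published
contingency table exactly (TP 101, FP 162 = 88 precision + 60 complication
+ 14 identical, FN 0, TN 933):

* identical: 918 same-code pairs plus 14 *medically* identical diagnoses
  coded to a sibling subcategory (2 steps) — the cases a step trigger
  flags although experts call them identical;
* precision: ancestor/descendant refinements, 10 at 1 step and 88 at
  2 steps;
* complication: same chapter, different block (30 at 4 and 30 at 6 steps),
  plus 5 whose follow-up letter still lists the index diagnosis, so their
  effective distance under the min-over-follow-ups rule is 0;
* diagnostically different: cross-chapter pairs at 6, 8 or 10 steps
  (roughly equal thirds);
* hierarchically different: cross-chapter pairs at mismatched depths —
  5 (block vs category), 7 (category vs subcategory), 9 steps
  (4-char vs 5-char subcategory). Using a block-range node as a coarse
  "diagnosis" is a modeling liberty: 5 cross-chapter steps requires depth
  combination {2, 3} (or {1, 4}).

What the generator does **not** emulate: the empirical within-category
step-distance distributions (unpublished — only cutoff-level aggregates are
printed), coding noise, rater disagreement (κ ≈ 0.4), patient covariates,
and the real study's deeper tree (its cutoff grid reaches 11 steps,
exceeding the 10-step diameter of a five-level hierarchy, suggesting an
extra level such as block groups in the original software). Consequently a
passing suite demonstrates that the *pipeline arithmetic* is right and
that the trigger separates the constructed categories; it does not
re-estimate the study's AUC of 0.94–0.95 — on the synthetic cohort the
steps AUC is ≈ 0.99 and the optimal cutoffs land at 5 rather than 2,
because the constructed discrepant pairs all sit at ≥ 5 steps while real
discrepant pairs evidently reach down to 2–3 steps.

## Numerical and design notes

* Largest-remainder allocation: floors plus one unit to the largest
  fractional parts; ties resolved by insertion order of the weights.
* All randomness flows through one `numpy.random.Generator` seeded per
  call; no global RNG state. Identical seeds give byte-identical outputs.
* Degrading a cohort removes follow-ups preferentially from pairs whose
  follow-up equals the index code: patients who needed no follow-up care
  are those whose diagnosis did not evolve. Discrepant pairs are never
  eligible. Labels are unchanged.
* Records CSV round-trips floats via `repr` (shortest exact
  representation), so write-then-read is bit-exact.
* Validation excludes unscored records (no follow-up, skipped unknown
  codes); the CLI logs how many were excluded. Problem sizes throughout
  the test suite and acceptance script are the study's own (n = 1,204;
  the 65-node miniature taxonomy), which keeps every check sub-second.

## Known limitations

* The miniature taxonomy is a synthetic four-chapter excerpt; real ICD-10
  has 22 chapters and code-range block membership that the TSV dialect
  states explicitly rather than inferring from range strings.
* No ICD national modifications (GM/CM), no ClaML parsing, no free-text
  coding, no harm classification, no ensemble of the four algorithms.
* DeLong CIs are asymptotic; at very small n or AUC near 1 the clipped
  normal interval is conservative. Bootstrap or exact intervals are out of
  scope.
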