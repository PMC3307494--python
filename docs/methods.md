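# Methods

## Model

`litrank` treats literature triage as two-class document classification
over dictionary keywords. Every abstract is a bag of canonical term IDs
with occurrence counts; the classifier is L2-regularized logistic
regression in its dual formulation (the LIBLINEAR solver family, reached
through scikit-learn's `LogisticRegression(solver="liblinear", dual=True)`),
with termination tolerance e = 0.1. The probability that abstract *x*
belongs to the interesting set A is σ(wᵀx + b). No kernel, no tf-idf, no
normalization: the feature value *is* the raw keyword count, and the
feature space *is* the set of keywords observed in the training abstracts.
These are deliberate modeling commitments, not omissions — the method's
premise is that typed dictionary keywords are already a strong, compact
representation of a biomedical abstract (~32 keywords on average in
pre-tagged corpora).

Assumptions worth stating:

* Keyword counts are informative and roughly comparable across abstracts;
  no length correction is applied.
* The training sets define relevance. Cross-validation accuracy on A∪B is
  therefore an *optimistic* estimate of accuracy on the query set C, whose
  distribution the model never sees.
* Duplicated abstracts (a gene list can hit the same paper repeatedly, and
  users repeat entries on purpose) are kept as repeated vectors; they act
  as implicit instance weights.

## Penalty tuning

The only tuned hyperparameter is the penalty C, searched in two fixed
stages under five-fold cross-validation:

* stage 1: C = 2^x for x = −3 … 4 (eight points);
* stage 2 (neighborhood of the best x), run exactly once, only when the
  training set is smaller than 5,000 vectors, or smaller than 10,000 with
  best stage-1 accuracy under 80%:

  | x | C = 2^x | neighborhood values |
  |---|---------|---------------------|
  | −3 | 0.125 | 0.05, 0.1, 0.15 |
  | −2 | 0.25 | 0.15, 0.2, 0.3, 0.35 |
  | −1 | 0.5 | 0.3, 0.4, 0.6, 0.7 |
  | 0 | 1.0 | 0.75, 1.25, 1.5 |
  | 1 | 2.0 | 1.5, 2.5, 3.0 |
  | 2 | 4.0 | 3.0, 3.5, 4.5, 5.0, 6.0 |
  | 3 | 8.0 | 6.0, 7.0, 9.0, 10.0, 11.0 |
  | 4 | 16.0 | 11.0, 12.0, 13.0, 14.0, 15.0 |

The winner is the C with maximal CV accuracy over all evaluated points.
Ties break toward the smallest C: deterministic, and conservative in the
sense of strongest regularization. Fold assignment is a per-label seeded
shuffle followed by round-robin dealing (stratified); the fold-assignment
policy is a design choice made here — stratification stabilizes the small
sets this method is typically run on, and seeding makes every job
reproducible. Bit-compatibility of probabilities with any particular
LIBLINEAR build is not promised; the contract is the probability
semantics, the grid, and the selection rules.

## Tagging policy

Dictionary matching is unspecified territory in most keyword pipelines, so
the policy is pinned down explicitly: case-insensitive, token-boundary
anchored, hyphens kept inside tokens, longest match wins, matches never
overlap, scan left to right. A surface form mapped to several term IDs
credits all of them once per occurrence (ambiguity is preserved; the
classifier can downweight noisy terms). Counts pool surface variants by
canonical term ID. Disabled keyword types are removed *after* matching, so
the segmentation of text never depends on the type selection; the two
"general biological" types (bio_term, bio_action) can never be disabled.
The matcher is a hand-written token-n-gram longest-match scanner —
dictionary lookup per window, longest window first — which is exact and
fast enough for corpora of the size this package targets.

## Defaults and thresholds

| parameter | default | meaning |
|---|---|---|
| assignment threshold | 0.5 (strict >) | scores exactly at the threshold go to B |
| whole-index report cutoff | 0.85 | headline lists in whole-index mode |
| input cap | 25,000 entries per list | genes or abstracts |
| tolerance e | 0.1 | solver termination |
| CV folds | 5 | penalty selection |
| mean keywords/abstract (synthetic) | 32 | matches pre-tagged corpora |

The B-list is ordered by ascending score so the most confidently
background-like abstracts lead; this mirror-image of the A-list ordering is
a presentation choice (either direction is defensible). Equal scores order
by ascending PMID.

Undefined evaluation ratios (e.g. precision when nothing is assigned to A)
are reported as explicitly undefined, never as 0, to keep curve extremes
honest. MCC uses the standard zero-denominator → 0 convention.

## Synthetic worlds

The generator emulates the statistics the pipeline cares about and nothing
more. Two topics draw keywords from multinomials over a vocabulary whose
topic-exclusive fraction is δ: each keyword draw uses the topic's exclusive
vocabulary with probability δ and a shared distribution (identical across
topics) otherwise, so δ = 0 gives a single common distribution and δ = 1
disjoint vocabularies. Keyword counts per abstract are Poisson with mean
32; keyword weights are Dirichlet draws with a concentration knob.
Synthetic genes link to Poisson-many abstracts of their own topic, with an
impurity knob for stress-testing expansion. Everything derives from one
seeded generator.

Emitted abstract *text* is the space-joined sequence of sampled surface
forms, with unique single-token surface forms, so text-mode tagging and
pretagged-mode profiles agree exactly; this is the cross-mode oracle used
in the tests. Multi-word and ambiguous surface forms are exercised by
hand-built dictionaries in the tagger tests instead.

What the worlds do **not** model: real English prose (word order, syntax,
negation), abbreviation ambiguity at realistic rates, topic drift over
time, citation structure, or MeSH-style annotation. Passing the synthetic
recovery tests therefore shows the pipeline machinery is sound — it does
not certify precision/recall on real literature, which depends on the
dictionary quality and corpus the user supplies.

Test problem sizes are chosen to exercise the statistics at small scale: a
δ = 1 world with 200 training abstracts per side and 200 held out checks
parameter recovery (held-out accuracy ≥ 0.9 expected); ten δ = 0 seeds
check that accuracy collapses to chance (0.5 ± 0.1) when no signal exists;
the random-background property uses a three-population construction
(two related topics plus a diffuse off-topic mass) because the
inflate-toward-A effect of a random background only manifests when the
query set is topical relative to the sampling universe.

## Degenerate inputs and numerical notes

* Abstracts with no text, or no in-vocabulary keywords, become zero
  vectors; they are kept and score the intercept-only probability.
* A gene with no Entrez mapping or no linked abstracts contributes nothing
  (logged); a set that ends up empty aborts the job.
* A CV fold holding a single class is still scored; a *training* split
  with a single class contributes no correct predictions for its fold.
* Duplicate PMIDs within a corpus file resolve to the last record, with a
  warning; duplicates within input sets are preserved by design.
* Fold assignment, background sampling and synthetic worlds all consume
  `numpy.random.default_rng` seeded from the job seed; reruns are
  byte-identical.

## Known limitations

* Live identifier resolution (Entrez utilities, Ensembl lookups, PubMed
  queries) is out of scope; mappings come from user-supplied tables, and
  PubMed-query inputs resolve only through a query→PMID fixture.
* One probability threshold governs assignment; no abstention band.
* Training cost grows with the grid (up to 13 penalty evaluations × 5
  folds); very large jobs should expect the refinement stage to be skipped
  by the size rule.
* The per-gene ordering of linked PMIDs follows link-table insertion
  order; no relevance ordering is implied within a gene's abstracts.
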