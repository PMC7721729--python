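# Methods

This note documents the models and procedures implemented in `phenoclust`,
the choices made where the design was genuinely open, and what the
synthetic-cohort tests do and do not establish.

## Input model

The unit of input is a *mention*: one occurrence of a normalized clinical
concept (a CUI-like code) in one patient's notes, with one or more semantic
types and an assertion polarity. The pipeline deliberately consumes only
the output of an upstream NLP extraction system; named-entity recognition,
concept normalization and negation detection are out of scope.

Complaint filtering keeps positively-asserted mentions whose semantic type
(case-insensitive) is in a whitelist of disease/sign/symptom-like types.
The shipped default whitelist (`corpus.DEFAULT_COMPLAINT_TYPES`, ten
UMLS-style type names) is a configurable stand-in — sites using a specific
ontology release should supply their own list. Concept identifiers are
treated as case-sensitive codes. Mentions whose concept is absent from the
vocabulary are dropped with a warning by default (strict mode raises):
ingestion should not silently absorb vocabulary drift, but neither should
one stray code abort a cohort build.

Aggregation sums mentions per (patient, concept) over the entire record —
no timeline features. Patients with zero surviving complaint mentions are
kept as all-zero rows through aggregation (so cohort accounting stays
honest) but excluded, with logging, before vectorization and clustering: an
empty complaint profile is not a phenotype, and an all-zero vector has no
direction on the unit sphere. Concepts observed in zero patients are
dropped (their IDF is undefined). No minimum document frequency is applied
by default (`min_df` is available).

## TF-IDF representation

Term frequency is the raw aggregated count; inverse document frequency uses
the smoothed convention `idf(c) = ln((1+N)/(1+df_c)) + 1`; rows are
L2-normalized. Rationale: this is the dominant modern TF-IDF default, the
smoothing keeps IDF finite and positive for ubiquitous concepts, and unit
rows make Euclidean K-means distance monotone in cosine similarity, which
is the natural notion of profile similarity here. All three choices are
exposed (`tf ∈ {raw, log1p}`, `idf ∈ {smooth, plain}`, `norm ∈ {l2,
none}`); whether to normalize before K-means is a declared package
decision, not an established fact about the reference analysis. The module
is fully deterministic.

## Clustering and stability selection

K-means uses k-means++ initialization, best of `n_init = 10` restarts,
`max_iter = 300`, relative tolerance `1e-4` (scikit-learn's Lloyd
implementation; empty clusters are relocated internally to farthest
points, so returned partitions never contain empty clusters). Per-K seeds
derive deterministically from one master seed via `SeedSequence`, so a
sweep is reproducible bit-for-bit and per-K results do not depend on which
other K values were swept.

Stability selection is clusterwise bootstrap in the spirit of Hennig's
`clusterboot`: for each of B resamples of patients with replacement, refit
K-means at the same K with a fresh derived seed; score each reference
cluster by the maximum Jaccard index between its patient set and any
bootstrap cluster's, both restricted to the unique patients drawn (Jaccard
is a set statistic; duplicates are collapsed). A reference cluster with no
member in a resample scores 0 for that replicate (it "dissolved").
Per-cluster stability is the mean over replicates; K is flagged stable iff
its least-stable cluster reaches the threshold. Defaults: `B = 100`,
threshold `0.75`, both exposed. Bootstrap refits use their own restart
count (`bootstrap_n_init = 5`, exposed) — a replicate needs a
representative local optimum, not the best-of-10, and `clusterboot`
itself refits with few restarts; reference fits keep `n_init = 10`.

**Known limitation.** Bootstrap stability is a *necessary*, not
sufficient, indicator of real cluster structure. On sparse count data
with heavy-tailed concept popularity — including this package's own
structureless null cohorts — patients occupy discrete presence-pattern
atoms of the dominant concepts, and K-means cuts along dominant popularity
axes reproduce almost perfectly under resampling. Mid-range K values can
therefore be flagged stable even when no phenotype structure was planted
(measured in `tests/test_acceptance.py`, which documents this behavior as
a deliberately failing expectation). On *isotropic* structureless noise
the selection behaves as intended (no stable K; covered in
`tests/test_clustering.py`). Stable K values should be read as "worth
characterizing", not as proof of distinct phenotypes; the enrichment
stage's error control is the statistical guard.

## Dendrogram

Levels are the stable K values in ascending order. Each cluster at one
level attaches to the cluster at the immediately preceding level with the
largest Jaccard overlap of patient sets; the branch length is `1 − J`.
Linking is greedy per child (not a global assignment) and only consecutive
levels are compared — this matches the pairwise `1 − J` construction and
keeps parents well-defined when cluster counts are not nested divisors.
Ties go to the lower cluster id and are logged. The root holds the whole
cohort; a first-level cluster's dissimilarity to the root is `1 − |C|/N`.
Newick export writes `K{K}_C{id}` names and the dissimilarities as branch
lengths; single-child chains are preserved (a cluster that persists across
levels appears at each level).

## Enrichment, summaries, associations

Per cluster and concept, a two-sample t-test of TF-IDF values, alternative
"cluster mean greater". Welch (unequal variances) is the default — cluster
sizes are routinely unequal — with the pooled test available. Family-wise
correction is Bonferroni with family size m = (concepts tested) ×
(clusters at this K), i.e. the full comparison family at one resolution.
Concepts with zero variance in both groups and equal means get p = 1 by
convention (logged); a normality diagnostic is not imposed — the tests are
reported as-is and the permutation-based family-wise error check in the
test suite is the operational guarantee. Top-concept lists sort by raw p
ascending (ties: larger t, then concept id) and truncate after filtering
at the adjusted-p threshold.

Cluster summaries use linear-interpolation percentiles, pairwise exclusion
of missing age/BMI, and report ICD-10 codes whose within-cluster frequency
exceeds a floor (default 5%).

The association score between two concepts is the Jaccard index of their
cohort-wide patient presence sets (count > 0); presence is deliberately
not restricted to cluster members, so the score measures co-occurrence in
the population, not within the stratum that selected the concepts (a
cluster-restricted variant and an external document × concept presence
table — e.g. a literature corpus — are accepted). Pairs among the union of
per-cluster top-10 concepts are labeled *within* when the two concepts
share at least one source cluster. The within > between comparison is a
one-sided Welch t-test; with all scores identical the p-value is 1 by
convention.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, at a scale that
keeps full runs in minutes: patients drawn from the leaves of a phenotype
tree; per-concept counts negative-binomial (dispersion `size = 1` by
default — clinical mentions are overdispersed through repeated
documentation) with mean = baseline × multiplier, where each leaf (and,
through shared signature sets, each supercluster) enriches its signature
concepts; negated mentions and non-complaint contaminant mentions injected
at 5% each so the ingestion filter is exercised; demographics, mortality
and ICD-10 codes sampled per leaf.

Baseline concept popularity is a truncated power law: exponent 1.0 with
per-concept mean counts capped at 5. This was chosen so the marginals look
like real complaint corpora at the emulated scale — the commonest
complaints are near-ubiquitous *across* patients yet average only a few
mentions *per* patient, and the median unique-concepts-per-patient on the
3,000 × 400 preset lands at ≈ 67 (cf. the ~72-of-1,276 scale of the
motivating cohort). A steeper exponent (1.5) concentrates ~38% of all
mention mass on one concept whose geometric count noise then dominates
every normalized patient vector, which neither resembles real corpora nor
admits recoverable structure at any plausible enrichment.

Presets: `paper_scale_mini` (3,000 patients × 400 concepts, 6 leaves under
2 superclusters, 10 shared + 10 private signature concepts per leaf at
multiplier 12, distinct demographic profiles) and `small_preset`
(600 × 120, 4 leaves) for unit tests.

What passing tests show: the pipeline recovers planted, well-separated
phenotypes (ARI ≥ 0.9 at the planted K), their two-level hierarchy, and
their signature concepts, with family-wise error control under a true
null. What they do not show: behavior under overlapping phenotypes,
longitudinal drift, coded-vocabulary noise, or realistic clinical language
— the generator plants clean multiplicative enrichments and has no visit
structure.

## Numerical and reproducibility choices

All stage seeds derive from one master seed by fixed `SeedSequence` keys
(kept below 2³¹). TSV outputs use `%.12g` floats; manifests record SHA-256
hashes of every output, and a rerun with an identical configuration is
byte-identical. Problem sizes used by the acceptance script: 3 structured
and 3 null cohorts at 3,000 × 400, B = 50 bootstrap replicates, 20
permutation replicates for the family-wise error rate — sizes chosen so a
complete from-scratch run stays within minutes on one core while keeping
Monte-Carlo error well inside the asserted margins.
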