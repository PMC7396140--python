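# Methods

`microko` implements a comparative microbiome analysis built around three
statistical procedures: (1) a KO paralog over-representation statistic with
functional-unit enrichment testing, (2) genus-composition comparison across
host animals with Euclidean hierarchical clustering, and (3) 16S amplicon
phylogenetics by neighbor joining on Kimura 2-parameter distances. A seeded
synthetic-data module supplies inputs with planted ground truth for every
stage.

## KO annotation and paralog counting

Inputs are 12-column tabular alignment reports (one per genome) from a
protein search against a KO reference. A gene's annotation is the KO of its
**top hit** — the first record per query in file order, since the aligners
that produce this format emit hits best-first — accepted only when its
e-value is **strictly below 1e-8** (`e_max`, configurable). Lower-ranked
hits are never consulted, even when they carry smaller e-values: the filter
selects among top hits, it does not re-rank. Identity and score cutoffs are
treated as properties of the upstream search, not re-checked here.

Per-genome paralog counts (genes per KO) are summarized to genus level as
the **median across the genus's strains**; with an even number of strains
the midpoint of the two central values is used, so genus profiles may carry
half-integers. A strain lacking a KO contributes a copy number of zero —
absence is data, not missingness. All strains of the focal group are pooled
into a single median rather than averaged species by species.

## KO ratio and enrichment testing

For each KO *i*, with a focal genus and a background set of genera:

    ratio_i = focal_median_i / mean_j(background_median_{i,j})
    log2fc_i = log2(ratio_i)

The background value is the arithmetic mean of the background genus medians
over a **shared KO universe** (the union of observed KOs; a KO that is zero
in the focal genus and all backgrounds is dropped from the universe).
`log2fc` is an extended real: −∞ at ratio 0 and +∞ where the background
mean is 0 but the focal median is not.

KOs with `log2fc ≥ 1.0` form the over-represented set. The boundary is
inclusive by default with a flag for strict comparison, since both
conventions appear in practice; the difference only matters for KOs landing
exactly on the threshold.

Each functional unit (KEGG module `Mxxxxx` or pathway `mapxxxxx`) is tested
with a **one-sided Fisher's exact test**. The four counts A (KOs in the
unit), B (KOs outside), C (over-represented KOs in the unit) and D
(over-represented KOs outside) are not a disjoint 2×2 table as stated —
C ⊆ A and D ⊆ B — so the test is run on the standard enrichment
reconstruction `[[C, A−C], [D, B−D]]`, equivalently the hypergeometric
upper tail P(X ≥ C) with population A+B, C+D successes and A draws
(`scipy.stats.hypergeom.sf`). One-sided "greater" is the default because
the question is over-representation only; a two-sided option exists.
Units whose members are disjoint from the universe are skipped with a
logged warning. Significance is `p ≤ 0.05` with **no multiple-testing
correction**, matching the procedure the pipeline reproduces; a
Benjamini–Hochberg q-value column is emitted for the user's benefit but
never drives the flag. Results are ordered by ascending p, ties broken by
unit id.

## Composition pipeline

Stage order: **filter → normalize → host-average → collapse → cluster**.

* Samples with total aligned counts **below 1,000** (strict) are removed.
* Counts become per-sample relative abundances (rows sum to 1 ± 1e-9).
* Host profiles are unweighted means of their samples' fractions —
  normalization before averaging makes the result invariant to sequencing
  depth.
* For presentation, the 10 genera with the largest mean abundance across
  hosts keep their columns; the rest are pooled into `others` (row sums
  preserved). Ranking uses the cross-host mean because per-host ranking
  yields unstable column sets.
* Hierarchical clustering uses pairwise **Euclidean distances** with
  average linkage (UPGMA) by default — the common choice for abundance
  heatmaps, with monotone merge heights — and flags for single, complete
  and Ward. Clustering operates on the full genus matrix, not the collapsed
  one; the collapse is output formatting. The same operation is reused to
  cluster genus-level KO paralog matrices. SciPy's deterministic merge
  ordering resolves distance ties.
* 16S copy-number normalization is deliberately off: the upstream counts
  this pipeline consumes are produced without it.

## Phylogeny stage

* **Trimming** follows the standard single-end semantics of
  LEADING:17 TRAILING:17 AVGQUAL:25 MINLEN:200, applied in that order per
  read: strip leading bases with quality < 17, strip trailing bases with
  quality < 17, drop the read if the surviving mean quality is < 25 or the
  surviving length < 200.
* **Dereplication** groups identical sequences and returns
  (sequence, count) sorted by descending count, ties broken
  lexicographically — the head of the list is the sample's most abundant
  unique sequence.
* **K2P distance**: with P and Q the transition and transversion fractions
  over usable sites, `d = −½·ln(1−2P−Q) − ¼·ln(1−2Q)`. Sites where either
  sequence has a gap or ambiguity code are excluded per pair (**pairwise
  deletion**, robust for partially overlapping amplicon alignments; a
  complete-deletion mode is not offered because the simulator emits gapless
  alignments and real inputs arrive pre-aligned). When the log arguments
  are non-positive the pair is saturated and the distance is +∞; matrices
  containing saturated pairs are returned with a warning, and tree building
  refuses them by name.
* **Neighbor joining** is the Saitou–Nei agglomeration with the Q-criterion
  `Q(i,j) = (n−2)·d(i,j) − r_i − r_j`. The Q matrix is computed with the
  symmetric sum `r_i + r_j` taken first so it is exactly symmetric in
  floating point, and ties are broken by the smallest (i, j) index pair —
  both choices make the output fully deterministic. Negative branch lengths
  are retained as computed, preserving exactness on additive matrices (NJ
  reproduces every input distance of an additive matrix along tree paths).
* **Outgroup rooting** places the root at the midpoint of the edge
  separating a monophyletic outgroup from the ingroup; a single-taxon
  outgroup always works, and a non-monophyletic multi-taxon outgroup is an
  error naming the offending split. Equivalence with any particular GUI
  implementation is claimed at the level of the algorithm's definition, not
  byte-identical trees, since gap handling and tie-breaking inside such
  tools are not documented.

## Synthetic data: what it emulates and what it does not

* **KO profiles**: background strain counts are Poisson(`background_mean`,
  default 1 — of the order of single-copy genes); focal strains draw KOs
  inside planted units from Poisson(fold × mean), default fold 4 and three
  planted units of 20 KOs among 100 disjoint units over 2,000 KOs, with
  9 background genera × 5 strains and 10 focal strains. Poisson is the
  minimal overdispersion-free model and keeps the planted fold-change
  directly interpretable; real pangenomes are overdispersed and have
  correlated gene families, so recovery here demonstrates correctness of
  the statistics, not power on real genomes. Units are disjoint in the
  simulator although real KEGG units overlap; overlap only affects the
  interpretation of per-unit tests, which the pipeline (like the procedure
  it implements) does not correct for.
* **Composition**: per sample, proportions ~ Dirichlet(host weights) and
  counts ~ Multinomial(total, proportions); totals are uniform in
  [5,000, 20,000] (a realistic amplicon depth) and a configurable number of
  samples are forced below the 1,000-count threshold to exercise the
  filter. A dominant-genus host (one weight ≫ others) emulates the
  single-genus-dominated community the pipeline is designed to flag.
* **Sequences**: gapless alignments evolved on a known tree with the exact
  closed-form K2P transition matrices per branch (exact at any branch
  length, unlike event-stepping simulation), root drawn uniform per site.
  No indels, rate variation or sequencing error — so NJ recovery rates here
  are upper bounds for real amplicons.
* **Reads**: quality arrays are specified exactly (constant, ramp or custom
  vector), making trimming behavior testable base by base.

Determinism: every generator is a pure function of (config, seed).
Per-strain/per-sample randomness uses spawned `SeedSequence` sub-streams,
so enlarging a dataset never changes earlier rows.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` validate at sizes where the
relevant asymptotics already hold: the exact-test oracle is exhaustive over
all ~136,000 tables with A+B ≤ 40; enrichment recovery and null calibration
use 100 seeds each at the default profile size; NJ exactness uses 100
random trees of 6–10 taxa; the K2P estimator uses 200 replicate pairs of
10,000 sites at true distance 0.15; composition clustering uses 20 seeded
two-host datasets. These sizes make the checks sharp (3-standard-error
bands, exact zero Robinson–Foulds totals) while keeping a full run in
seconds.

## Known limitations

* The enrichment test treats KOs as exchangeable units; phylogenetic
  correlation between strains of a genus is absorbed by the median, not
  modeled.
* No multiple-testing correction drives significance (by design, to match
  the reproduced procedure); users screening many units should consult the
  BH column.
* NJ on saturated (infinite) K2P distances is refused rather than patched;
  sequences that diverged beyond the model's domain need a different
  distance or model.
* The CLI's `all` subcommand runs on the simulator's outputs; real analyses
  run the stage subcommands on user-supplied files.
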