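# Methods

## Problem and approach

The package addresses a two-class transcriptomic classification problem:
given normalized RNA-seq read counts for tumor samples from two tissue
sites (e.g. primary melanoma vs regional cutaneous/subcutaneous
metastases), find small gene sets whose expression separates the classes,
rank genes by how consistently they are selected, and follow up candidate
markers with co-expression and miRNA-target analyses.

Expression values are log2-transformed with a floor at one
(`log2(max(v, 1))`) and not otherwise normalized; the floor maps the
sub-count noise range [0, 1] exactly to zero. The transform is applied
once; a state flag on the matrix guards against double application.
Missing values are rejected outright — the intended inputs (level-3-style
matrices) are complete, and imputation is out of scope.

## GA/KNN

**Classifier.** k-nearest neighbors (default k = 5, required odd) with
majority vote, on Euclidean distance over per-gene standardized values.
Standardization statistics are always computed from the training samples
in play: for a held-out sample in LOOCV, the mean and unbiased SD of each
gene are recomputed over the remaining n − 1 samples. Standardization can
be disabled (`standardize: false` / `--no-standardize`) since the
literature is ambiguous on this point; the default is to standardize,
which makes the distance scale-free across genes. Degenerate cases are
defined rather than left to chance: distance ties break by ascending
training-sample index; a tied vote (possible only for even k) takes the
single nearest neighbor's label; a gene with zero training variance
contributes nothing to the distance.

**Fitness.** The LOOCV accuracy of a gene set on the training fold. The
implementation evaluates whole populations vectorized, using the identity
that the distance from held-out sample i to training sample t under
fold-i standardization is Σ_g (x_gt − x_gi)² / var_g^(−i), with the
leave-one-out means and variances precomputed in closed form from the
per-gene sums and sums of squares. Variances below 10⁻¹² are treated as
zero. A brute-force oracle (explicit re-standardization and sorting per
held-out sample) reproduces the vectorized fitness exactly on random
instances; this equivalence is asserted in the test suite.

**Genetic algorithm.** Chromosomes are L-gene *sets* (order is meaningless
to k-NN), so crossover and mutation repair duplicates by substituting
random unused genes. Per generation: fitness evaluation (with caching of
repeated chromosomes), elitism (default 2), rank-proportional parent
selection (selection weight proportional to 1..P by ascending fitness),
uniform crossover (rate 0.9), and slot-wise mutation (rate 0.05) to a
random gene not in the chromosome. A run terminates at the first
chromosome whose fitness reaches `fitness_threshold` — the *near-optimal*
criterion — or returns the best chromosome at the generation cap; which
criterion fired is recorded on the returned set (`hit_threshold`). The
original method leaves the operator suite and near-optimality definition
open; these defaults are declared in the configuration and logged, so
every run is auditable and reproducible. Two shipped configurations:
`configs/paper.yaml` (L = 20, population 300, 1000 generations, k = 5,
5000 sets per partition, threshold 0.95) for full-scale cohorts, and
`configs/desk.yaml` (L = 5, population 50, 60 generations, 50 sets,
threshold 0.9) for laptop-scale synthetic experiments.

**Reproducibility.** One master seed; GA run r on partition p draws from
the RNG substream (seed, p, r), so runs are independent and the whole
pipeline is bit-reproducible regardless of execution order.

## Resampled evaluation

Samples are split into training (75%) and testing (25%) sets, by default
stratified per class with round-half-up rounding (a 74 + 66 cohort gives
56 + 50 = 106 training, 34 testing; unstratified splitting is available
for the literal "randomly divided" reading). One hundred independent
partitions are drawn by default, so each sample appears ~75 times in
training and ~25 in testing. On each partition the GA collects its quota
of near-optimal sets from the training fold; every training sample is then
scored by LOOCV within the fold and every testing sample by k-NN against
the full fold, under each collected set. A sample's per-partition score is
the *fraction* of sets classifying it correctly (the alternative —
binarizing each partition's majority call — is coarser and discards the
set-level information); its overall training/testing accuracy is the mean
over its appearances in that role. Summaries report min, Q1, median, mean,
Q3, max per class group and overall, with quartiles by linear
interpolation between order statistics (the numpy/R type-7 default).
Gene-frequency ranking counts occurrences over all sets and partitions,
descending, ties broken lexicographically.

## Co-expression and rank aggregation

Spearman correlation is Pearson on midranks (scipy's implementation,
cross-checked in the tests against an independent midrank + Pearson
route); constant vectors return a flagged NaN. Per-group and pooled
correlations against the anchor gene are computed by ranking each sample
block once and correlating rank vectors; the "average" column is the
unweighted mean of per-group r values. Group comparisons use Welch's
unequal-variance t test by default (pooled-variance available by flag):
the safer choice when group variances are unknown. Cross-dataset
aggregation ranks genes within each dataset by descending correlation
(midranks for ties), then scores each gene by the geometric mean of its
per-dataset ranks — the rank product, a parameter-free "robust ranking"
— with median rank as an alternative. Ranks are sorted per gene before
combining so the score is exactly invariant to dataset order. Genes absent
from any dataset are dropped (rank products are undefined for missing
ranks), with the count logged.

## Seed-site scanning

The seed is the first `seed_length` (default 8) nucleotides of the mature
miRNA 5'→3', starting at a configurable offset (default position 1; the
position-2 convention is a flag, since both exist in the field). A window
of the target read 5'→3' is paired antiparallel: target position
start + L − 1 − j against seed position j. Pairs are classified
Watson–Crick (A:U, U:A, G:C, C:G), G:U wobble, or mismatch. A site is
declared when WC + min(GU, max_gu) ≥ min_complementary (defaults 7 of 8
with at most one countable wobble — extra wobbles count as mismatches,
the most literal reading of "one G:U pairing allowed"). All qualifying
windows are reported, overlaps included, each window once; only the given
strand is scanned. DNA input (T) is normalized to U; other IUPAC codes are
hard errors. Machine output uses 0-based half-open coordinates (stated in
the file header); no thermodynamic, conservation or 3'-supplementary
scoring is applied.

## Synthetic data

`simulate_expression` draws background gene g as Normal(μ_g, σ²) on the
log2 scale with μ_g ~ Uniform[2, 10] (a realistic log2-CPM range);
informative genes add +δ to the second class; correlated genes are
ρ·z_anchor + √(1−ρ²)·ε against the anchor's standardized deviations, so ρ
is the population correlation. Defaults mirror a primary-vs-cutaneous
melanoma cohort: class sizes (74, 66), 20,000 genes, 10 informative genes
at δ = 1 (a two-fold change), σ = 1, an anchor with a 20-gene block at
ρ = 0.8. The generator emulates the *statistical structure* the analysis
assumes — two labelled classes, additive log-scale effects, a correlated
block — and deliberately not the messier features of real cohorts:
count-scale dispersion (values are Gaussian in log space, not negative
binomial), batch effects, tumor-purity gradients, gene–gene correlation
beyond the single anchor block, or class-imbalanced effect directions.
Tests passing on this generator therefore demonstrate that the machinery
is correct and calibrated, not that real cohorts will separate as cleanly.
`simulate_utr` plants exact reverse-complement seed windows and
single-wobble variants at non-overlapping random positions in uniform
ACGU background (1000 placement attempts before erroring), recording every
interval in a truth file.

## Problem sizes in the tests and acceptance script

The shipped experiments run at desk scale, chosen so the full suite
completes in minutes on one CPU while keeping every statistical property
testable: planted-signal recovery uses G = 300 genes, 5 informative at
δ = 2σ, n = 60 + 60, with the desk configuration and 4 partitions × 50
sets (200 collected sets) per seeded run, repeated over 10 seeds; the
null calibration permutes labels and uses 1 partition × 8 sets per seed
(null GA runs always hit the generation cap, making them the slow case);
oracle-equivalence checks use 100 random classification instances and
200–1000 random 500-nt sequences. Full-scale settings are shipped in
`configs/paper.yaml` but are not exercised by the tests.

## Behavior under the null, and a known accuracy ceiling

Two null-related facts are worth stating. First, the *held-out* test
accuracy of the full pipeline on label-permuted data is at chance (~0.49
over 10 seeds) — the calibration that matters. Second, the *training*
fitness of collected sets on permuted labels is far above 0.5 (~0.78 at
desk scale): the GA maximizes LOOCV accuracy over billions of candidate
sets, and best-of-search fitness under the null reflects strong selection
bias. This optimism is inherent to wrapper feature selection and is the
reason evaluation rests on held-out partitions rather than training
fitness.

Relatedly, stopping each GA run at the *first* chromosome to reach the
fitness threshold ties the quality of collected sets to that threshold:
with the desk threshold of 0.9, collected sets average ~0.92 training
fitness and ~0.88 held-out accuracy on δ = 2σ planted data, even though
the planted five-gene set itself scores 0.96–1.0 and gene recovery is
perfect. Raising the threshold (or the full-scale 0.95 default) yields
stronger sets at more search cost; the threshold is a quality floor, not
a target the sets exceed by much.

## Limitations

Only two-class problems are supported (multi-class selection is a
non-goal). No ROC/AUC machinery — evaluation is accuracy-based. No
GO-term enrichment, no download clients for expression portals, no
thermodynamic miRNA scoring. The GA parallelizes trivially over runs but
the implementation is single-process.
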