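# metasig

Gene-signature discovery for metastatic progression of cutaneous melanoma —
and, more generally, for any two-class bulk RNA-seq comparison. The package
implements three analyses around a single question: *which genes distinguish
primary tumors from regional metastases, and how might a candidate marker be
regulated?*

1. **GA/KNN feature selection with resampled evaluation.** A genetic
   algorithm searches for fixed-size gene sets ("chromosomes" of L genes)
   whose fitness is the leave-one-out cross-validated accuracy of a
   k-nearest-neighbor classifier on a training matrix. Many near-optimal
   sets are collected over many random 75/25 train/test partitions; each
   sample's accuracy is the average fraction of sets classifying it
   correctly over its ~75 training and ~25 testing appearances, and genes
   are ranked by how often they are selected.
2. **Anchor-gene co-expression.** Spearman correlation of every gene with a
   designated anchor gene (per tissue-site group and pooled), |r| ≥ 0.5
   selection, Welch t tests between groups, and robust cross-dataset rank
   aggregation by rank product (geometric mean of per-dataset ranks).
3. **miRNA seed-site scanning.** A combinatorial scan of mRNA/3'UTR
   sequences for windows antiparallel-complementary to a miRNA seed
   (default: seed length 8, ≥ 7 of 8 complementary, at most one G:U wobble
   counted as complementary).

A synthetic-data module generates two-class log2-scale expression matrices
with planted class-separating genes and an anchor-correlated gene block,
and UTR-like sequences with planted seed sites, so the whole pipeline is
testable without any external downloads.

## The model

For a gene set *S* with |S| = L, samples are compared by Euclidean distance
on per-gene standardized log2 expression, with gene means and SDs estimated
on the training samples in play (for LOOCV, recomputed with the held-out
sample excluded). The fitness of *S* is

    f(S) = (1/n) Σᵢ 1[ knn(xᵢ; X₋ᵢ restricted to S, k) = yᵢ ]

i.e. the leave-one-out accuracy of the k-NN majority vote (k = 5 by
default, odd, ties broken by the nearest neighbor; distance ties by sample
index). The GA evolves a population of L-subsets under rank-proportional
selection, uniform crossover with duplicate repair, slot-wise mutation and
elitism, stopping at the first chromosome with f(S) ≥ threshold (a
"near-optimal" set) or at the generation cap. Input matrices are
log2(max(v, 1))-transformed normalized read counts, with no further
normalization.

## Worked example

```python
from metasig import GAConfig, SignatureSelection, simulate_expression

matrix, truth = simulate_expression(
    n_per_class=(60, 60), n_genes=300, n_informative=5,
    delta=2.0, sigma=1.0, n_correlated=0, seed=7,
)
print("planted:", truth.informative_genes)

results = SignatureSelection(
    matrix, GAConfig.desk_scale(), n_partitions=4, seed=7
).fit()
print(results.summary().round(3).to_string(index=False))
print(results.gene_frequency().head(8).to_string(index=False))
print("mean test accuracy:", round(results.mean_accuracy("test"), 3))
```

Output:

```
planted: ['G0000', 'G0001', 'G0002', 'G0003', 'G0004']
     set     group   min    q1  median  mean    q3  max
training   primary 0.707 0.875   0.970 0.923 0.991  1.0
training cutaneous 0.560 0.872   0.960 0.919 0.990  1.0
training   Overall 0.560 0.872   0.960 0.921 0.990  1.0
 testing   primary 0.580 0.745   0.928 0.861 0.978  1.0
 testing cutaneous 0.640 0.840   0.905 0.890 0.980  1.0
 testing   Overall 0.580 0.800   0.920 0.874 0.980  1.0
gene_id  count  rank
  G0002     97     1
  G0001     82     2
  G0004     76     3
  G0000     70     4
  G0003     44     5
  G0142      8     6
  G0129      7     7
  G0292      6     8
mean test accuracy: 0.874
```

Reading it: over 4 random 75/25 partitions × 50 collected gene sets, the
six-number summary shows the usual training-over-testing bias (training
mean 0.921 vs testing mean 0.874), and all five planted class-separating
genes head the selection-frequency ranking, far ahead of the background
(counts 44–97 vs ≤ 8 of 200 sets).

The same workflow is available from the shell:

```bash
metasig simulate expr --n-per-class 60 60 --n-genes 300 --n-informative 5 \
    --delta 2 --seed 7 --out-prefix sim
metasig evaluate --matrix sim.matrix.tsv --labels sim.labels.tsv \
    --config configs/desk.yaml --partitions 4 --seed 7 --out results/
metasig scan --fasta utr.fa --mirna-seq UGAUUGGUACGUCUGUGGGUAG --out sites.tsv
```

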