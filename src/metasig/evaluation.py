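"""Resampled evaluation of GA/KNN signatures.

The estimation scheme: draw many (default 100) independent random 75/25
train/test partitions; on each training fold collect many near-optimal
gene sets with the GA; score every sample against every collected set —
training samples by leave-one-out cross-validation within the fold,
testing samples by k-NN against the whole fold; then average each
sample's per-partition correct-classification fractions over its ~75
training and ~25 testing appearances.  Genes are ranked by how often they
are selected across all sets and partitions.

:class:`SignatureSelection` packages the scheme as a model object whose
:meth:`~SignatureSelection.fit` returns a :class:`SignatureSelectionResults`
carrying the per-sample accuracies, the six-number summary per tissue-site
group, and the gene-frequency ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .gaknn import GAConfig, FeatureSet, TrainingFold, _evolve, _check_two_classes

logger = logging.getLogger(__name__)

__all__ = [
    "Partition",
    "SampleAccuracy",
    "make_partitions",
    "classify_with_sets",
    "aggregate_accuracy",
    "summarize_accuracy",
    "rank_genes_by_frequency",
    "SignatureSelection",
    "SignatureSelectionResults",
]


@dataclass
class Partition:
    """One random train/test split of the sample ids."""

    partition_id: int
    train_ids: list[str]
    test_ids: list[str]
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets overlap")


@dataclass
class SampleAccuracy:
    """Per-sample accuracies averaged over a sample's appearances in each role."""

    sample_id: str
    train_accuracy: float | None
    test_accuracy: float | None
    n_train_appearances: int
    n_test_appearances: int


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def make_partitions(
    labels: dict[str, str],
    n_partitions: int = 100,
    train_fraction: float = 0.75,
    seed: int = 0,
    *,
    stratify: bool = True,
) -> list[Partition]:
    """Draw independent random train/test partitions of the labelled samples.

    By default the split is stratified: each class contributes
    ``round_half_up(train_fraction * n_class)`` samples to training, which
    preserves the class balance in every fold.  ``stratify=False`` splits
    the pooled sample list instead.
    """
    samples = list(labels)
    n = len(samples)
    if n < 8:
        raise ValueError("need at least 8 labelled samples")
    by_class: dict[str, list[str]] = {}
    for s, c in labels.items():
        by_class.setdefault(c, []).append(s)
    if any(len(v) < 2 for v in by_class.values()):
        small = [c for c, v in by_class.items() if len(v) < 2]
        raise ValueError(f"class(es) with fewer than 2 samples: {small}")
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must be in (0, 1)")

    partitions = []
    for p in range(n_partitions):
        rng = np.random.default_rng([seed, p])
        train: list[str] = []
        test: list[str] = []
        if stratify:
            for c in sorted(by_class):
                members = sorted(by_class[c])
                n_train = _round_half_up(train_fraction * len(members))
                n_train = min(max(n_train, 1), len(members) - 1)
                perm = rng.permutation(len(members))
                train += [members[i] for i in perm[:n_train]]
                test += [members[i] for i in perm[n_train:]]
        else:
            members = sorted(samples)
            n_train = _round_half_up(train_fraction * n)
            n_train = min(max(n_train, 1), n - 1)
            perm = rng.permutation(n)
            train = [members[i] for i in perm[:n_train]]
            test = [members[i] for i in perm[n_train:]]
        partitions.append(
            Partition(partition_id=p, train_ids=sorted(train), test_ids=sorted(test), seed=seed)
        )
    return partitions


def classify_with_sets(
    sets: list[FeatureSet],
    matrix: ExpressionMatrix,
    partition: Partition,
    k: int = 5,
    *,
    standardize: bool = True,
) -> dict[str, float]:
    """Fraction of feature sets classifying each sample correctly, for one
    partition.

    Training samples are scored by LOOCV within the training fold; testing
    samples by k-NN against the full training fold.
    """
    if not sets:
        raise ValueError("no feature sets given")
    y_all, classes = _check_two_classes(matrix)
    gene_pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    chroms = []
    for fs in sets:
        missing = [g for g in fs.genes if g not in gene_pos]
        if missing:
            raise KeyError(f"feature-set gene(s) not in matrix: {missing}")
        chroms.append([gene_pos[g] for g in fs.genes])
    chroms = np.asarray(chroms, dtype=np.intp)

    sample_pos = {s: j for j, s in enumerate(matrix.sample_ids)}
    tr_idx = np.array([sample_pos[s] for s in partition.train_ids], dtype=np.intp)
    te_idx = np.array([sample_pos[s] for s in partition.test_ids], dtype=np.intp)

    fold = TrainingFold(matrix.values[:, tr_idx], y_all[tr_idx], standardize=standardize)
    fractions: dict[str, float] = {}

    train_pred = fold.loocv_predictions(chroms, k)  # (P, n_train)
    train_frac = (train_pred == y_all[tr_idx][None, :]).mean(axis=0)
    for s, f in zip(partition.train_ids, train_frac):
        fractions[s] = float(f)

    if len(te_idx):
        test_pred = fold.predict(chroms, matrix.values[:, te_idx], k)  # (P, n_test)
        test_frac = (test_pred == y_all[te_idx][None, :]).mean(axis=0)
        for s, f in zip(partition.test_ids, test_frac):
            fractions[s] = float(f)
    return fractions


def aggregate_accuracy(
    partitions: list[Partition],
    per_partition_fractions: list[dict[str, float]],
) -> list[SampleAccuracy]:
    """Average each sample's correct-classification fractions over its
    training and testing appearances.

    A sample that never appears in a role has that role's accuracy flagged
    absent (None).
    """
    train_acc: dict[str, list[float]] = {}
    test_acc: dict[str, list[float]] = {}
    for part, fracs in zip(partitions, per_partition_fractions):
        for s in part.train_ids:
            train_acc.setdefault(s, []).append(fracs[s])
        for s in part.test_ids:
            test_acc.setdefault(s, []).append(fracs[s])
    out = []
    for s in sorted(set(train_acc) | set(test_acc)):
        tr = train_acc.get(s, [])
        te = test_acc.get(s, [])
        out.append(
            SampleAccuracy(
                sample_id=s,
                train_accuracy=float(np.mean(tr)) if tr else None,
                test_accuracy=float(np.mean(te)) if te else None,
                n_train_appearances=len(tr),
                n_test_appearances=len(te),
            )
        )
    return out


def _six_number(values: np.ndarray) -> dict[str, float]:
    # quartiles use linear interpolation between order statistics ("type 7")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {
        "min": float(np.min(values)),
        "q1": float(q1),
        "median": float(med),
        "mean": float(np.mean(values)),
        "q3": float(q3),
        "max": float(np.max(values)),
    }


def summarize_accuracy(
    accuracies: list[SampleAccuracy],
    labels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Six-number summary (min, Q1, median, mean, Q3, max) of per-sample
    train and test accuracies, per class group and overall."""
    if not accuracies:
        raise ValueError("no accuracies to summarize")
    rows = []
    groups: dict[str, list[SampleAccuracy]] = {}
    if labels:
        for a in accuracies:
            groups.setdefault(labels.get(a.sample_id, "unlabelled"), []).append(a)
    groups["Overall"] = list(accuracies)
    for role, attr in (("training", "train_accuracy"), ("testing", "test_accuracy")):
        for group in groups:
            vals = np.array(
                [getattr(a, attr) for a in groups[group] if getattr(a, attr) is not None]
            )
            if vals.size == 0:
                continue
            row = {"set": role, "group": group}
            row.update(_six_number(vals))
            rows.append(row)
    return pd.DataFrame(rows, columns=["set", "group", "min", "q1", "median", "mean", "q3", "max"])


def rank_genes_by_frequency(all_sets: list[FeatureSet]) -> pd.DataFrame:
    """Count each gene's occurrences across all collected feature sets and
    rank by descending count (ties broken lexicographically by gene id)."""
    if not all_sets:
        raise ValueError("no feature sets collected")
    counts: dict[str, int] = {}
    for fs in all_sets:
        for g in fs.genes:
            counts[g] = counts.get(g, 0) + 1
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        [(g, c, r + 1) for r, (g, c) in enumerate(ordered)],
        columns=["gene_id", "count", "rank"],
    )


# ---------------------------------------------------------------------------
# Model / Results surface


class SignatureSelection:
    """GA/KNN signature selection with resampled train/test evaluation.

    Parameters
    ----------
    matrix : ExpressionMatrix
        log2-scale two-class expression matrix with a label for every sample.
    config : GAConfig
        GA and classifier settings; ``config.n_sets`` near-optimal sets are
        collected per partition.
    n_partitions : int
        Number of independent random train/test partitions (default 100).
    train_fraction : float
        Fraction of samples assigned to training per partition (default 0.75).
    stratify : bool
        Preserve class balance in every fold (default True).
    seed : int
        Master seed; partition p, run r uses RNG substream (seed, p, r).
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        config: GAConfig | None = None,
        *,
        n_partitions: int = 100,
        train_fraction: float = 0.75,
        stratify: bool = True,
        seed: int = 0,
    ):
        if not matrix.log2_transformed:
            logger.warning("matrix is not flagged log2-transformed; fitting on raw values")
        self.matrix = matrix
        self.config = config if config is not None else GAConfig()
        self.n_partitions = n_partitions
        self.train_fraction = train_fraction
        self.stratify = stratify
        self.seed = seed
        _check_two_classes(matrix)

    def fit(self) -> "SignatureSelectionResults":
        """Run the full resampled selection/evaluation pipeline."""
        matrix, config = self.matrix, self.config
        y_all, classes = _check_two_classes(matrix)
        partitions = make_partitions(
            matrix.labels,
            n_partitions=self.n_partitions,
            train_fraction=self.train_fraction,
            seed=self.seed,
            stratify=self.stratify,
        )
        sample_pos = {s: j for j, s in enumerate(matrix.sample_ids)}
        all_sets: list[FeatureSet] = []
        per_partition_sets: list[list[FeatureSet]] = []
        per_partition_fracs: list[dict[str, float]] = []

        for part in partitions:
            tr_idx = np.array([sample_pos[s] for s in part.train_ids], dtype=np.intp)
            fold = TrainingFold(
                matrix.values[:, tr_idx], y_all[tr_idx], standardize=config.standardize
            )
            sets = []
            for run in range(config.n_sets):
                rng = np.random.default_rng([self.seed, part.partition_id, run])
                sets.append(_evolve(fold, matrix.gene_ids, config, rng, run))
            per_partition_sets.append(sets)
            all_sets.extend(sets)
            per_partition_fracs.append(
                classify_with_sets(
                    sets, matrix, part, config.k, standardize=config.standardize
                )
            )
            logger.info(
                "partition %d/%d: %d sets, mean fitness %.3f",
                part.partition_id + 1, self.n_partitions, len(sets),
                float(np.mean([fs.fitness for fs in sets])),
            )

        accuracies = aggregate_accuracy(partitions, per_partition_fracs)
        return SignatureSelectionResults(
            model=self,
            partitions=partitions,
            feature_sets=per_partition_sets,
            sample_accuracies=accuracies,
        )


@dataclass
class SignatureSelectionResults:
    """Fitted results: collected gene sets, per-sample accuracies, summaries."""

    model: SignatureSelection
    partitions: list[Partition]
    feature_sets: list[list[FeatureSet]] = field(repr=False)
    sample_accuracies: list[SampleAccuracy] = field(repr=False)

    @property
    def all_sets(self) -> list[FeatureSet]:
        return [fs for sets in self.feature_sets for fs in sets]

    def sample_accuracy_frame(self) -> pd.DataFrame:
        labels = self.model.matrix.labels
        return pd.DataFrame(
            [
                {
                    "sample_id": a.sample_id,
                    "class": labels.get(a.sample_id),
                    "train_accuracy": a.train_accuracy,
                    "test_accuracy": a.test_accuracy,
                    "n_train_appearances": a.n_train_appearances,
                    "n_test_appearances": a.n_test_appearances,
                }
                for a in self.sample_accuracies
            ]
        )

    def gene_frequency(self) -> pd.DataFrame:
        return rank_genes_by_frequency(self.all_sets)

    def top_genes(self, n: int = 10) -> list[str]:
        return list(self.gene_frequency()["gene_id"].head(n))

    def summary(self) -> pd.DataFrame:
        """Six-number classification-performance table per group and overall."""
        return summarize_accuracy(self.sample_accuracies, self.model.matrix.labels)

    def mean_accuracy(self, role: str = "test") -> float:
        attr = {"train": "train_accuracy", "test": "test_accuracy"}[role]
        vals = [getattr(a, attr) for a in self.sample_accuracies if getattr(a, attr) is not None]
        return float(np.mean(vals))

    def save(self, outdir) -> None:
        """Write sample_accuracy.tsv, summary.tsv, gene_frequency.tsv and
        partitions.json under ``outdir``."""
        import json
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.sample_accuracy_frame().to_csv(out / "sample_accuracy.tsv", sep="\t", index=False)
        self.summary().to_csv(out / "summary.tsv", sep="\t", index=False)
        self.gene_frequency().to_csv(out / "gene_frequency.tsv", sep="\t", index=False)
        with open(out / "partitions.json", "w") as fh:
            json.dump(
                [
                    {
                        "partition_id": p.partition_id,
                        "train_ids": p.train_ids,
                        "test_ids": p.test_ids,
                        "seed": p.seed,
                    }
                    for p in self.partitions
                ],
                fh,
            )
        with open(out / "feature_sets.jsonl", "w") as fh:
            for pid, sets in enumerate(self.feature_sets):
                for fs in sets:
                    rec = fs.to_dict()
                    rec["partition_id"] = pid
                    fh.write(json.dumps(rec) + "\n")
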