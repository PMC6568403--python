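"""GA/KNN engine: evolve fixed-size gene sets scored by leave-one-out
cross-validated k-nearest-neighbor accuracy.

The method is a wrapper feature selector: a genetic algorithm searches the
space of L-gene subsets ("chromosomes"); the fitness of a subset is the
LOOCV accuracy of a k-NN classifier restricted to those genes on the
training matrix.  Many near-optimal subsets are collected across repeated
runs and genes are later ranked by how often they are selected
(:mod:`metasig.evaluation`).

Distances are Euclidean on per-gene standardized values; standardization
statistics (mean and SD) are always estimated on the training samples in
play — for LOOCV this means they are recomputed with the held-out sample
excluded.  Distance ties are broken by ascending training-sample index, and
a tied vote (only possible with even k) falls back to the label of the
single nearest neighbor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .expression import ExpressionMatrix

__all__ = [
    "GAConfig",
    "FeatureSet",
    "knn_predict",
    "loocv_fitness",
    "evolve_one",
    "collect_feature_sets",
    "TrainingFold",
]

_VAR_EPS = 1e-12


@dataclass
class GAConfig:
    """Genetic-algorithm and classifier settings.

    Defaults are the full-scale analysis settings: 20-gene chromosomes, a
    population of 300, up to 1000 generations, 5-nearest-neighbor majority
    vote, and 5000 collected near-optimal sets per training matrix.
    ``desk()`` gives a reduced configuration sized for laptop-scale
    synthetic experiments.
    """

    chromosome_length: int = 20
    population_size: int = 300
    max_generations: int = 1000
    k: int = 5
    n_sets: int = 5000
    fitness_threshold: float = 0.95
    mutation_rate: float = 0.05
    crossover_rate: float = 0.9
    elitism_count: int = 2
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chromosome_length < 1:
            raise ValueError("chromosome_length must be >= 1")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError("k must be odd and >= 1")
        # 0 is admitted as the vacuous threshold (any chromosome qualifies)
        if not (0 <= self.fitness_threshold <= 1):
            raise ValueError("fitness_threshold must be in [0, 1]")
        for name in ("mutation_rate", "crossover_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.elitism_count < 0 or self.elitism_count >= self.population_size:
            raise ValueError("elitism_count must be in [0, population_size)")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")
        if self.n_sets < 0:
            raise ValueError("n_sets must be >= 0")

    @classmethod
    def paper_scale(cls, **overrides) -> "GAConfig":
        """Full-scale settings (L=20, P=300, 1000 generations, 5000 sets)."""
        return cls(**overrides)

    @classmethod
    def desk_scale(cls, **overrides) -> "GAConfig":
        """Reduced settings for synthetic desk-scale experiments."""
        defaults = dict(
            chromosome_length=5,
            population_size=50,
            max_generations=60,
            k=5,
            n_sets=50,
            fitness_threshold=0.9,
        )
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def from_yaml(cls, path) -> "GAConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class FeatureSet:
    """One evolved gene set and its LOOCV fitness.

    ``hit_threshold`` records which stopping criterion fired: True if the
    near-optimal fitness threshold was reached, False if the generation cap
    returned the best chromosome found.
    """

    genes: tuple[str, ...]
    fitness: float
    generation_found: int
    run_index: int
    hit_threshold: bool = True
    history: list[float] | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("feature set contains duplicate genes")
        self.genes = tuple(sorted(self.genes))
        if not (0.0 <= self.fitness <= 1.0):
            raise ValueError("fitness must be in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "genes": list(self.genes),
            "fitness": self.fitness,
            "generation_found": self.generation_found,
            "run_index": self.run_index,
            "hit_threshold": self.hit_threshold,
        }


# ---------------------------------------------------------------------------
# Vectorized k-NN / LOOCV machinery


def _majority_vote(nbr_labels: np.ndarray, k: int) -> np.ndarray:
    """Majority vote over 0/1 neighbor labels (last axis, ascending distance).

    A tied vote (even k only) takes the label of the nearest neighbor.
    """
    votes = nbr_labels.sum(axis=-1)
    pred = (2 * votes > k).astype(np.int64)
    if k % 2 == 0:
        tie = 2 * votes == k
        pred[tie] = nbr_labels[..., 0][tie]
    return pred


class TrainingFold:
    """Precomputed standardization statistics for one training matrix.

    Holds the full gene matrix for a training fold plus the leave-one-out
    mean/variance of every gene (the statistics for held-out sample ``i``
    are computed over the remaining ``n - 1`` samples), so that LOOCV
    fitness of many chromosomes can be evaluated in one vectorized pass.
    """

    def __init__(self, values: np.ndarray, y: np.ndarray, standardize: bool = True):
        X = np.asarray(values, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[1] != y.shape[0]:
            raise ValueError("values must be (n_genes, n_samples) matching labels")
        n = X.shape[1]
        if n < 3:
            raise ValueError("training fold needs at least 3 samples")
        self.X = X
        self.y = y.astype(np.int64)
        self.n = n
        self.standardize = standardize

        S = X.sum(axis=1)
        SS = (X * X).sum(axis=1)
        mean_ex = (S[:, None] - X) / (n - 1)
        # unbiased variance over the n-1 retained samples
        var_ex = (SS[:, None] - X * X - (n - 1) * mean_ex * mean_ex) / (n - 2)
        self._w_excl = np.where(var_ex > _VAR_EPS, 1.0 / np.maximum(var_ex, _VAR_EPS), 0.0)

        mean_full = S / n
        var_full = (SS - n * mean_full * mean_full) / (n - 1)
        self._w_full = np.where(var_full > _VAR_EPS, 1.0 / np.maximum(var_full, _VAR_EPS), 0.0)

    def loocv_predictions(self, chroms: np.ndarray, k: int) -> np.ndarray:
        """LOOCV k-NN prediction of every fold sample, for a batch of chromosomes.

        Parameters
        ----------
        chroms : int ndarray, shape (P, L)
            Gene row indices of each chromosome.
        k : int
            Neighbors; must satisfy ``k <= n - 1``.

        Returns
        -------
        int ndarray, shape (P, n) of predicted 0/1 labels.
        """
        chroms = np.atleast_2d(np.asarray(chroms, dtype=np.intp))
        if k > self.n - 1:
            raise ValueError(f"k={k} exceeds the {self.n - 1} training samples left by LOOCV")
        Xg = self.X[chroms]  # (P, L, n)
        d = Xg[:, :, :, None] - Xg[:, :, None, :]  # d[p,l,i,t] = x_i - x_t
        d *= d
        if self.standardize:
            W = self._w_excl[chroms]  # (P, L, n)
            D2 = np.einsum("pli,plit->pit", W, d)
        else:
            D2 = d.sum(axis=1)
        idx = np.arange(self.n)
        D2[:, idx, idx] = np.inf  # a sample is never its own neighbor
        order = np.argsort(D2, axis=-1, kind="stable")[:, :, :k]
        return _majority_vote(self.y[order], k)

    def loocv_fitness(self, chroms: np.ndarray, k: int) -> np.ndarray:
        """Fraction of fold samples LOOCV-classified correctly, per chromosome."""
        pred = self.loocv_predictions(chroms, k)
        return (pred == self.y[None, :]).mean(axis=1)

    def predict(self, chroms: np.ndarray, queries: np.ndarray, k: int) -> np.ndarray:
        """k-NN prediction of held-out query profiles against the whole fold.

        ``queries`` is (n_genes, m) indexed like the fold matrix; returns
        (P, m) predicted 0/1 labels.
        """
        chroms = np.atleast_2d(np.asarray(chroms, dtype=np.intp))
        if k > self.n:
            raise ValueError(f"k={k} exceeds the {self.n} training samples")
        Q = np.asarray(queries, dtype=float)
        Xg = self.X[chroms]  # (P, L, n)
        Qg = Q[chroms]  # (P, L, m)
        d = Qg[:, :, :, None] - Xg[:, :, None, :]  # (P, L, m, n)
        d *= d
        if self.standardize:
            W = self._w_full[chroms]  # (P, L)
            D2 = np.einsum("pl,plmt->pmt", W, d)
        else:
            D2 = d.sum(axis=1)
        order = np.argsort(D2, axis=-1, kind="stable")[:, :, :k]
        return _majority_vote(self.y[order], k)


def _check_two_classes(matrix: ExpressionMatrix) -> tuple[np.ndarray, list[str]]:
    labels = matrix.label_array()
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError(f"expected exactly two classes, found {classes}")
    y = (labels == classes[1]).astype(np.int64)
    return y, classes


def knn_predict(
    train: ExpressionMatrix,
    query_profile: np.ndarray,
    k: int = 5,
    *,
    standardize: bool = True,
) -> str:
    """Classify one expression profile by majority vote of its k nearest
    training samples (Euclidean distance on per-gene standardized values).

    ``train`` must already be restricted to the feature-set genes; the query
    profile is given in the same gene order.
    """
    query = np.asarray(query_profile, dtype=float)
    if query.shape != (train.n_genes,):
        raise ValueError(
            f"query profile length {query.shape} does not match {train.n_genes} genes"
        )
    if k > train.n_samples:
        raise ValueError(f"k={k} exceeds the {train.n_samples} training samples")
    labels = train.label_array()
    classes = sorted(set(labels))
    if len(classes) == 1:
        return classes[0]  # degenerate: unanimous vote
    y, classes = _check_two_classes(train)
    X = train.values
    if standardize:
        mean = X.mean(axis=1)
        sd = X.std(axis=1, ddof=1)
        w = np.where(sd * sd > _VAR_EPS, 1.0 / np.maximum(sd * sd, _VAR_EPS), 0.0)
    else:
        w = np.ones(train.n_genes)
    diff = X - query[:, None]
    d2 = (w[:, None] * diff * diff).sum(axis=0)
    order = np.argsort(d2, kind="stable")[:k]
    pred = _majority_vote(y[order][None, :], k)[0]
    return classes[pred]


def loocv_fitness(
    train: ExpressionMatrix,
    genes,
    k: int = 5,
    *,
    standardize: bool = True,
) -> float:
    """Leave-one-out cross-validated k-NN accuracy of a gene set.

    Each training sample is predicted from all the others, with the
    standardization statistics recomputed excluding the held-out sample.
    """
    genes = list(genes)
    y, _ = _check_two_classes(train)
    rows = [train.gene_index(g) for g in genes]
    fold = TrainingFold(train.values[rows], y, standardize=standardize)
    chrom = np.arange(len(rows))[None, :]
    return float(fold.loocv_fitness(chrom, k)[0])


# ---------------------------------------------------------------------------
# Genetic algorithm


def _chrom_key(chrom: np.ndarray) -> bytes:
    return np.sort(chrom).tobytes()


def _repair(chrom: np.ndarray, n_genes: int, rng: np.random.Generator) -> np.ndarray:
    """Replace duplicate slots with random genes not already in the chromosome."""
    seen: set[int] = set()
    dup_slots = []
    for j, g in enumerate(chrom):
        if int(g) in seen:
            dup_slots.append(j)
        else:
            seen.add(int(g))
    for j in dup_slots:
        g = int(rng.integers(n_genes))
        while g in seen:
            g = int(rng.integers(n_genes))
        chrom[j] = g
        seen.add(g)
    return chrom


def _evolve(
    fold: TrainingFold,
    gene_ids: list[str],
    config: GAConfig,
    rng: np.random.Generator,
    run_index: int,
    track_history: bool = False,
) -> FeatureSet:
    n_genes = len(gene_ids)
    L, P = config.chromosome_length, config.population_size
    if n_genes < L:
        raise ValueError(f"gene universe ({n_genes}) smaller than chromosome length ({L})")

    pop = np.stack([rng.choice(n_genes, size=L, replace=False) for _ in range(P)])
    cache: dict[bytes, float] = {}
    history: list[float] = []
    best_chrom, best_fit, best_gen = None, -1.0, 0

    for gen in range(config.max_generations):
        keys = [_chrom_key(c) for c in pop]
        new_idx = [i for i, key in enumerate(keys) if key not in cache]
        if new_idx:
            fits = fold.loocv_fitness(pop[new_idx], config.k)
            for i, f in zip(new_idx, fits):
                cache[keys[i]] = float(f)
        fitness = np.array([cache[key] for key in keys])

        gen_best = int(np.argmax(fitness))
        if fitness[gen_best] > best_fit:
            best_fit = float(fitness[gen_best])
            best_chrom = pop[gen_best].copy()
            best_gen = gen
        if track_history:
            history.append(best_fit)
        if best_fit >= config.fitness_threshold:
            return FeatureSet(
                genes=tuple(gene_ids[g] for g in best_chrom),
                fitness=best_fit,
                generation_found=best_gen,
                run_index=run_index,
                hit_threshold=True,
                history=history if track_history else None,
            )

        # rank-proportional parent selection (weight = 1..P by ascending fitness)
        order = np.argsort(fitness, kind="stable")
        weights = np.empty(P)
        weights[order] = np.arange(1, P + 1)
        probs = weights / weights.sum()

        elite_idx = np.argsort(-fitness, kind="stable")[: config.elitism_count]
        children = [pop[i].copy() for i in elite_idx]
        while len(children) < P:
            a, b = rng.choice(P, size=2, p=probs)
            pa, pb = pop[a], pop[b]
            if rng.random() < config.crossover_rate:
                mask = rng.random(L) < 0.5
                child = np.where(mask, pa, pb).copy()
                child = _repair(child, n_genes, rng)
            else:
                child = pa.copy()
            # slot-wise mutation to a random gene not in the chromosome
            mut = np.flatnonzero(rng.random(L) < config.mutation_rate)
            present = set(int(g) for g in child)
            for j in mut:
                g = int(rng.integers(n_genes))
                while g in present:
                    g = int(rng.integers(n_genes))
                present.discard(int(child[j]))
                child[j] = g
                present.add(g)
            children.append(child)
        pop = np.stack(children)

    return FeatureSet(
        genes=tuple(gene_ids[g] for g in best_chrom),
        fitness=best_fit,
        generation_found=best_gen,
        run_index=run_index,
        hit_threshold=False,
        history=history if track_history else None,
    )


def evolve_one(
    train: ExpressionMatrix,
    config: GAConfig,
    *,
    run_index: int = 0,
    rng: np.random.Generator | None = None,
    track_history: bool = False,
) -> FeatureSet:
    """Run one GA search and return the first near-optimal gene set found
    (or the best set at the generation cap)."""
    y, _ = _check_two_classes(train)
    fold = TrainingFold(train.values, y, standardize=config.standardize)
    if rng is None:
        rng = np.random.default_rng([config.seed, run_index])
    return _evolve(fold, train.gene_ids, config, rng, run_index, track_history)


def collect_feature_sets(
    train: ExpressionMatrix,
    config: GAConfig,
    *,
    seed: int | None = None,
) -> list[FeatureSet]:
    """Collect ``config.n_sets`` near-optimal feature sets from independent
    GA runs (RNG substream ``(seed, run_index)`` per run; duplicates allowed
    — downstream gene-frequency ranking counts them)."""
    y, _ = _check_two_classes(train)
    fold = TrainingFold(train.values, y, standardize=config.standardize)
    master = config.seed if seed is None else seed
    sets = []
    for run_index in range(config.n_sets):
        rng = np.random.default_rng([master, run_index])
        sets.append(_evolve(fold, train.gene_ids, config, rng, run_index))
    return sets
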