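"""Synthetic inputs with the statistical structure the analysis assumes.

Two generators:

* :func:`simulate_expression` — a two-class log2-scale expression matrix
  with a small set of class-separating genes of controllable effect size
  and a block of genes correlated with a designated anchor gene.  It stands
  in for a primary-vs-cutaneous-metastasis melanoma cohort, so the default
  class sizes are 74 and 66 samples.
* :func:`simulate_utr` — random 3'UTR-like RNA sequences with planted
  miRNA seed-complementary sites (perfect or carrying one G:U wobble),
  with a truth record of every planted interval.

Both are deterministic given their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .expression import ExpressionMatrix
from .mirna import SeedSpec, reverse_complement_rna

__all__ = [
    "SyntheticTruth",
    "SyntheticSequenceTruth",
    "simulate_expression",
    "simulate_utr",
    "write_truth_json",
]


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated expression matrix."""

    informative_genes: list[str]
    delta: float
    sigma: float
    anchor_gene: str
    correlated_genes: list[str]
    rho: float
    seed: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticSequenceTruth:
    """Planted seed-site intervals: (sequence_id, start, end, site_kind).

    Intervals are 0-based half-open on the target read 5'->3'; ``site_kind``
    is ``"perfect"`` (all 8 Watson-Crick pairs) or ``"one_GU"`` (7 WC plus
    one G:U wobble).
    """

    planted_sites: list[tuple[str, int, int, str]] = field(default_factory=list)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "planted_sites": [list(s) for s in self.planted_sites],
            "seed": self.seed,
        }


def write_truth_json(truth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2)


def simulate_expression(
    n_per_class: tuple[int, int] = (74, 66),
    n_genes: int = 20000,
    n_informative: int = 10,
    delta: float = 1.0,
    sigma: float = 1.0,
    n_correlated: int = 20,
    rho: float = 0.8,
    seed: int = 0,
    class_labels: tuple[str, str] = ("primary", "cutaneous"),
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate a two-class log2-scale expression matrix.

    Background gene ``g`` is Normal(mu_g, sigma^2) with baseline mu_g drawn
    uniformly in [2, 10] (a realistic log2-CPM range).  Informative genes
    additionally shift the second class by ``+delta``.  Correlated genes are
    built as ``rho * z_anchor + sqrt(1 - rho^2) * noise`` against the anchor
    gene's standardized deviations, giving population correlation ``rho``.
    The anchor, informative and correlated gene sets are disjoint.

    Returns the matrix (``log2_transformed`` set: values are already on the
    log scale) and a :class:`SyntheticTruth` record.
    """
    n0, n1 = n_per_class
    if min(n0, n1) < 4:
        raise ValueError("each class needs at least 4 samples")
    if n_informative < 0 or n_correlated < 0:
        raise ValueError("gene counts must be non-negative")
    if n_informative + n_correlated + 1 > n_genes:
        raise ValueError(
            f"gene budget infeasible: {n_informative} informative + "
            f"{n_correlated} correlated + 1 anchor > {n_genes} genes"
        )
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if abs(rho) > 1:
        raise ValueError("|rho| must be <= 1")

    rng = np.random.default_rng([seed, 0])
    n = n0 + n1
    width = max(4, len(str(n_genes)))
    gene_ids = [f"G{i:0{width}d}" for i in range(n_genes)]
    sample_ids = [f"S{j:04d}" for j in range(n)]
    y = np.array([0] * n0 + [1] * n1)

    mu = rng.uniform(2.0, 10.0, size=n_genes)
    values = mu[:, None] + sigma * rng.standard_normal((n_genes, n))

    # gene roles: informative first, then the anchor, then its correlated block
    informative = gene_ids[:n_informative]
    anchor = gene_ids[n_informative]
    correlated = gene_ids[n_informative + 1 : n_informative + 1 + n_correlated]

    values[:n_informative, y == 1] += delta

    a_row = n_informative
    z_anchor = (values[a_row] - mu[a_row]) / sigma
    for i in range(n_correlated):
        row = a_row + 1 + i
        eps = rng.standard_normal(n)
        values[row] = mu[row] + sigma * (rho * z_anchor + np.sqrt(1 - rho**2) * eps)

    labels = {s: class_labels[c] for s, c in zip(sample_ids, y)}
    matrix = ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=values,
        labels=labels,
        log2_transformed=True,
    )
    truth = SyntheticTruth(
        informative_genes=informative,
        delta=delta,
        sigma=sigma,
        anchor_gene=anchor,
        correlated_genes=list(correlated),
        rho=rho,
        seed=seed,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# UTR sequences with planted seed sites

_RNA = np.array(list("ACGU"))
# seed base -> target base making a G:U wobble instead of the WC pair
_GU_SUBSTITUTION = {"U": "G", "G": "U"}


def _plant_window(spec: SeedSpec, kind: str, rng: np.random.Generator) -> str:
    """The target-strand window (5'->3') for one planted site."""
    seed = spec.seed_sequence
    window = reverse_complement_rna(seed)  # perfect antiparallel WC match
    if kind == "perfect":
        return window
    if kind == "one_GU":
        eligible = [j for j, b in enumerate(seed) if b in _GU_SUBSTITUTION]
        if not eligible:
            raise ValueError(
                "seed contains no G or U, so a G:U-wobble site cannot be planted"
            )
        j = int(rng.choice(eligible))
        # seed position j pairs with window position seed_length-1-j
        pos = len(seed) - 1 - j
        chars = list(window)
        chars[pos] = _GU_SUBSTITUTION[seed[j]]
        return "".join(chars)
    raise ValueError(f"unknown site kind {kind!r}")


def simulate_utr(
    n_sequences: int = 1,
    length: int = 500,
    seed_spec: SeedSpec | None = None,
    n_perfect: int = 2,
    n_one_gu: int = 1,
    seed: int = 0,
) -> tuple[list[SeqRecord], SyntheticSequenceTruth]:
    """Simulate 3'UTR-like RNA sequences with planted miRNA seed sites.

    Each sequence is uniform random ACGU background; ``n_perfect`` exact
    reverse-complement windows of the seed and ``n_one_gu`` windows carrying
    exactly one G:U substitution are planted per sequence at random
    non-overlapping positions (1000 placement attempts before giving up).
    """
    if seed_spec is None:
        raise ValueError("seed_spec is required")
    if length < seed_spec.seed_length:
        raise ValueError("sequence length must be >= seed length")
    rng = np.random.default_rng([seed, 1])
    slen = seed_spec.seed_length
    records: list[SeqRecord] = []
    truth = SyntheticSequenceTruth(seed=seed)

    for s in range(n_sequences):
        seq_id = f"utr{s:03d}"
        chars = rng.choice(_RNA, size=length)
        taken: list[tuple[int, int]] = []
        kinds = ["perfect"] * n_perfect + ["one_GU"] * n_one_gu
        for kind in kinds:
            placed = False
            for _ in range(1000):
                start = int(rng.integers(0, length - slen + 1))
                end = start + slen
                if all(end <= a or start >= b for a, b in taken):
                    taken.append((start, end))
                    window = _plant_window(seed_spec, kind, rng)
                    chars[start:end] = list(window)
                    truth.planted_sites.append((seq_id, start, end, kind))
                    placed = True
                    break
            if not placed:
                raise ValueError(
                    f"could not place a non-overlapping {kind} site in {seq_id} "
                    f"after 1000 attempts"
                )
        records.append(
            SeqRecord(Seq("".join(chars)), id=seq_id, description="synthetic 3'UTR")
        )

    truth.planted_sites.sort()
    return records, truth
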