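"""Expression-matrix container and I/O.

The pipeline works on genes x samples matrices of normalized RNA-seq read
counts (counts per million mapped reads, TCGA level-3 style).  The only
transformation applied is ``log2(max(v, 1))`` — values below one are floored
at one so that the log scale starts at zero — with no further normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "log2_floor_transform",
    "read_expression_tsv",
    "read_labels_tsv",
    "write_expression_tsv",
    "write_labels_tsv",
]


def log2_floor_transform(raw: np.ndarray) -> np.ndarray:
    """log2-transform normalized read counts, flooring values below 1 at 1.

    Every value ``v`` maps to ``log2(max(v, 1))``, so the output is
    non-negative and finite; inputs in ``[0, 1]`` map exactly to 0.

    Parameters
    ----------
    raw : ndarray
        Non-negative normalized read counts.

    Raises
    ------
    ValueError
        If any value is negative or non-finite.
    """
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("expression values must be finite")
    if np.any(raw < 0):
        raise ValueError("expression values must be non-negative read counts")
    return np.log2(np.maximum(raw, 1.0))


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix with per-sample class labels.

    Attributes
    ----------
    gene_ids : list of str
        Unique gene identifiers (opaque strings; no symbol remapping).
    sample_ids : list of str
        Unique sample identifiers.
    values : ndarray, shape (n_genes, n_samples)
        Expression values; on log2 scale once ``log2_transformed`` is True.
    labels : dict
        Map sample_id -> class label.  Classification requires exactly two
        distinct labels covering every sample.
    log2_transformed : bool
        Set once :meth:`log2_floor` has been applied; guards against
        double transformation.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    labels: dict[str, str] = field(default_factory=dict)
    log2_transformed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValueError(f"duplicate gene ids: {dupes}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise ValueError(f"duplicate sample ids: {dupes}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains NaN/Inf; missing values are not supported")
        unknown = set(self.labels) - set(self.sample_ids)
        if unknown:
            raise ValueError(f"labels refer to unknown samples: {sorted(unknown)}")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not in matrix") from None

    def label_array(self) -> np.ndarray:
        """Class label per sample, in sample order.  Requires full coverage."""
        missing = [s for s in self.sample_ids if s not in self.labels]
        if missing:
            raise ValueError(f"samples without class label: {missing}")
        return np.array([self.labels[s] for s in self.sample_ids])

    def classes(self) -> list[str]:
        """The distinct class labels, sorted."""
        return sorted(set(self.labels.values()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    # -- transformation ----------------------------------------------------

    def log2_floor(self) -> "ExpressionMatrix":
        """Return a copy with :func:`log2_floor_transform` applied once.

        Raises
        ------
        ValueError
            If the matrix is already on the log2 scale.
        """
        if self.log2_transformed:
            raise ValueError("matrix is already log2-transformed")
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=list(self.sample_ids),
            values=log2_floor_transform(self.values),
            labels=dict(self.labels),
            log2_transformed=True,
        )

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=list(sample_ids),
            values=self.values[:, idx],
            labels={s: self.labels[s] for s in sample_ids if s in self.labels},
            log2_transformed=self.log2_transformed,
        )


def read_labels_tsv(path) -> dict[str, str]:
    """Read a two-column (sample_id, class) TSV into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"label file {path} needs two tab-separated columns")
    # Tolerate an optional header row
    if df.iloc[0, 0] in ("sample_id", "sample"):
        df = df.iloc[1:]
    if df[0].duplicated().any():
        dupes = sorted(df[0][df[0].duplicated()].unique())
        raise ValueError(f"duplicate sample ids in label file: {dupes}")
    return dict(zip(df[0], df[1]))


def read_expression_tsv(path, label_path=None, *, log2_transformed: bool = False) -> ExpressionMatrix:
    """Read a level-3-style expression TSV (header = sample ids, column 1 = gene id).

    Samples with no entry in the label file are dropped with a logged
    warning; duplicate gene or sample ids and non-numeric cells are hard
    errors naming the offender.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicate gene ids in {path}: {dupes}")
    if df.columns.duplicated().any():
        dupes = sorted(df.columns[df.columns.duplicated()].unique())
        raise ValueError(f"duplicate sample ids in {path}: {dupes}")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce")
        if bad.isna().any():
            row = df.index[bad.isna()][0]
            raise ValueError(f"non-numeric value at gene {row!r}, sample {col!r} in {path}")
    values = df.to_numpy(dtype=float)

    labels: dict[str, str] = {}
    sample_ids = list(map(str, df.columns))
    if label_path is not None:
        all_labels = read_labels_tsv(label_path)
        kept = [s for s in sample_ids if s in all_labels]
        dropped = [s for s in sample_ids if s not in all_labels]
        if dropped:
            logger.warning(
                "dropping %d sample(s) absent from label file: %s", len(dropped), dropped
            )
        col_idx = [sample_ids.index(s) for s in kept]
        values = values[:, col_idx]
        sample_ids = kept
        labels = {s: all_labels[s] for s in kept}

    return ExpressionMatrix(
        gene_ids=list(map(str, df.index)),
        sample_ids=sample_ids,
        values=values,
        labels=labels,
        log2_transformed=log2_transformed,
    )


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    """Write the matrix in the same TSV layout :func:`read_expression_tsv` reads.

    Values are printed in full repr precision so a write/read round trip is
    lossless.
    """
    df = matrix.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def write_labels_tsv(labels: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for sample, cls in labels.items():
            fh.write(f"{sample}\t{cls}\n")
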