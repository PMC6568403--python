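"""Anchor-gene co-expression: Spearman correlation per group and pooled,
threshold selection, group-difference t test, and robust cross-dataset
rank aggregation.

The co-expression analysis asks which genes track a designated anchor gene
(e.g. GPC6) across samples: Spearman correlations are computed within each
tissue-site group and pooled over all samples, genes beyond |r| thresholds
are selected, and ranks of correlation from several datasets (tumor types,
cell-line panels) are combined by rank product — the geometric mean of a
gene's per-dataset ranks — or, alternatively, by median rank.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "spearman",
    "correlate_anchor",
    "select_by_threshold",
    "two_sample_ttest",
    "aggregate_ranks",
]


def spearman(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of midranked values.

    Returns NaN (flagged missing) when either vector is constant, for which
    rank correlation is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant vector: Spearman correlation undefined, returning NaN")
        return float("nan")
    r = stats.spearmanr(x, y).statistic
    return float(r)


def correlate_anchor(
    matrix: ExpressionMatrix,
    anchor: str,
    groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Spearman correlation of every gene with the anchor gene.

    Returns a table with one row per gene: pooled correlation over all
    samples (``r_pooled``), per-group correlations (``r_<group>``) when a
    sample->group map is given, and their unweighted mean (``average_r``).
    """
    a_row = matrix.gene_index(anchor)  # KeyError if absent
    X = matrix.values
    anchor_vals = X[a_row]

    def _corr_block(cols: np.ndarray) -> np.ndarray:
        # rank once per block, then Pearson of ranks against the anchor ranks
        sub = X[:, cols]
        ranks = stats.rankdata(sub, axis=1)
        ar = ranks[a_row]
        ar_c = ar - ar.mean()
        rc = ranks - ranks.mean(axis=1, keepdims=True)
        denom = np.sqrt((rc * rc).sum(axis=1) * (ar_c * ar_c).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (rc @ ar_c) / denom
        return r  # NaN where a gene (or the anchor) is constant in the block

    out = pd.DataFrame({"gene_id": matrix.gene_ids})
    out["r_pooled"] = _corr_block(np.arange(matrix.n_samples))

    group_cols = []
    if groups is not None:
        by_group: dict[str, list[int]] = {}
        for j, s in enumerate(matrix.sample_ids):
            if s in groups:
                by_group.setdefault(groups[s], []).append(j)
        for g in sorted(by_group):
            cols = np.array(by_group[g])
            if cols.size < 3:
                raise ValueError(f"group {g!r} has fewer than 3 samples")
            col = f"r_{g}"
            out[col] = _corr_block(cols)
            group_cols.append(col)
    if group_cols:
        out["average_r"] = out[group_cols].mean(axis=1)
    else:
        out["average_r"] = out["r_pooled"]
    out.attrs["anchor_gene"] = anchor
    return out


def select_by_threshold(
    table: pd.DataFrame,
    r_min: float = 0.5,
    r_max: float = -0.5,
) -> tuple[list[str], list[str]]:
    """Genes whose pooled correlation with the anchor passes the thresholds.

    Returns (positive, negative): pooled r >= r_min and <= r_max
    respectively, anchor excluded from both, each sorted by descending |r|.
    """
    if not (r_max <= 0 <= r_min):
        raise ValueError("thresholds must satisfy r_max <= 0 <= r_min")
    anchor = table.attrs.get("anchor_gene")
    t = table[table["gene_id"] != anchor]
    pos = t[t["r_pooled"] >= r_min].sort_values("r_pooled", ascending=False)
    neg = t[t["r_pooled"] <= r_max].sort_values("r_pooled", ascending=True)
    return list(pos["gene_id"]), list(neg["gene_id"])


def two_sample_ttest(x, y, *, equal_var: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t test (Welch by default; pooled-variance with
    ``equal_var=True``).  Returns (t statistic, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def aggregate_ranks(
    tables: list[pd.DataFrame],
    *,
    method: str = "geometric",
    r_column: str = "r_pooled",
) -> pd.DataFrame:
    """Aggregate per-dataset correlation ranks into an overall ranking.

    Within each dataset genes are ranked by descending correlation with the
    anchor (average rank for ties).  The aggregate score is the geometric
    mean of a gene's per-dataset ranks (rank product normalized by the D-th
    root; ``method="median"`` uses the median rank instead); overall ranks
    are assigned by ascending score with lexicographic tie-break.  Genes
    absent from any dataset are dropped (logged).
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 datasets to aggregate")
    if method not in ("geometric", "median"):
        raise ValueError("method must be 'geometric' or 'median'")

    common = set(tables[0]["gene_id"])
    union = set(tables[0]["gene_id"])
    for t in tables[1:]:
        common &= set(t["gene_id"])
        union |= set(t["gene_id"])
    if not common:
        raise ValueError("no genes shared by all datasets")
    dropped = len(union) - len(common)
    if dropped:
        logger.info("dropping %d gene(s) absent from at least one dataset", dropped)

    genes = sorted(common)
    rank_cols = {}
    for d, t in enumerate(tables):
        sub = t[t["gene_id"].isin(common)].set_index("gene_id")[r_column].reindex(genes)
        # descending r -> rank 1 is the most positively correlated gene
        rank_cols[f"rank_{d}"] = pd.Series(
            stats.rankdata(-sub.to_numpy()), index=genes
        )
    out = pd.DataFrame(rank_cols, index=genes)
    # sort each gene's ranks before combining so the score is exactly
    # invariant to dataset order (floating summation is order-sensitive)
    ranks = np.sort(out.to_numpy(), axis=1)
    if method == "geometric":
        score = np.exp(np.log(ranks).mean(axis=1))
    else:
        score = np.median(ranks, axis=1)
    out.insert(0, "gene_id", genes)
    out["score"] = score
    out = out.sort_values(["score", "gene_id"], kind="stable").reset_index(drop=True)
    out["overall_rank"] = np.arange(1, len(out) + 1)
    return out
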