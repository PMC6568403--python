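import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metasig import (
    ExpressionMatrix,
    aggregate_ranks,
    correlate_anchor,
    select_by_threshold,
    simulate_expression,
    spearman,
    two_sample_ttest,
)


def _midrank_pearson(x, y):
    """Independent route: midrank both vectors by hand, then np.corrcoef."""
    def midranks(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v), dtype=float)
        i = 0
        sv = np.asarray(v)[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    return np.corrcoef(midranks(x), midranks(y))[0, 1]


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3], [2, 4, 6]) == 1.0

    def test_perfect_inverse(self):
        assert spearman([1, 2, 3], [6, 4, 2]) == -1.0

    def test_single_transposition_closed_form(self):
        """x=[1,2,3,4], y=[1,3,2,4]: 1 - 6*Sum(d^2)/(n(n^2-1)) = 1 - 12/60 = 0.8."""
        assert spearman([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8, abs=1e-12)

    def test_constant_vector_returns_flagged_missing(self):
        assert np.isnan(spearman([1, 1, 1], [1, 2, 3]))

    def test_equals_pearson_on_midranks_with_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(5, 30))
            x = rng.integers(0, 6, size=n).astype(float)  # heavy ties
            y = rng.integers(0, 6, size=n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            assert spearman(x, y) == pytest.approx(_midrank_pearson(x, y), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        r = spearman(x, y)
        assert spearman(np.exp(x), y) == pytest.approx(r, abs=1e-12)
        assert spearman(x, 3 * y + 2) == pytest.approx(r, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [1, 2])


class TestCorrelateAnchor:
    def test_anchor_correlates_perfectly_with_itself(self):
        m, t = simulate_expression(n_per_class=(10, 10), n_genes=20, n_informative=0,
                                   n_correlated=3, rho=0.5, seed=0)
        table = correlate_anchor(m, t.anchor_gene)
        r_self = table.set_index("gene_id").loc[t.anchor_gene, "r_pooled"]
        assert r_self == pytest.approx(1.0)

    def test_correlated_block_recovered_at_threshold(self):
        """rho=0.8 at n=200: the planted block passes r >= 0.5."""
        m, t = simulate_expression(n_per_class=(100, 100), n_genes=60, n_informative=0,
                                   n_correlated=15, rho=0.8, seed=4)
        table = correlate_anchor(m, t.anchor_gene)
        pos, _ = select_by_threshold(table, 0.5, -0.5)
        assert set(t.correlated_genes) <= set(pos)

    def test_missing_anchor_is_hard_error(self, tiny_matrix):
        with pytest.raises(KeyError, match="nope"):
            correlate_anchor(tiny_matrix, "nope")

    def test_group_signs_can_differ_while_pooled_attenuates(self):
        """A gene correlated with the anchor in one group and anti-correlated
        in the other has opposite per-group r and attenuated pooled |r|."""
        rng = np.random.default_rng(9)
        n = 40
        anchor = rng.normal(size=2 * n)
        gene = np.concatenate([anchor[:n], -anchor[n:]])
        m = ExpressionMatrix(
            gene_ids=["anchor", "flip"],
            sample_ids=[f"s{i}" for i in range(2 * n)],
            values=np.vstack([anchor, gene]),
        )
        groups = {f"s{i}": ("g1" if i < n else "g2") for i in range(2 * n)}
        table = correlate_anchor(m, "anchor", groups).set_index("gene_id")
        r1, r2 = table.loc["flip", "r_g1"], table.loc["flip", "r_g2"]
        assert r1 == pytest.approx(1.0) and r2 == pytest.approx(-1.0)
        assert abs(table.loc["flip", "r_pooled"]) < 0.5
        assert table.loc["flip", "average_r"] == pytest.approx((r1 + r2) / 2)

    def test_per_group_matches_direct_spearman(self):
        m, t = simulate_expression(n_per_class=(15, 15), n_genes=10, n_informative=0,
                                   n_correlated=2, rho=0.6, seed=11)
        groups = m.labels
        table = correlate_anchor(m, t.anchor_gene, groups).set_index("gene_id")
        a_row = m.values[m.gene_index(t.anchor_gene)]
        cols = [j for j, s in enumerate(m.sample_ids) if groups[s] == "primary"]
        g = t.correlated_genes[0]
        direct = spearman(a_row[cols], m.values[m.gene_index(g)][cols])
        assert table.loc[g, "r_primary"] == pytest.approx(direct, abs=1e-12)


class TestSelectByThreshold:
    def _table(self):
        t = pd.DataFrame({"gene_id": ["anchor", "g1", "g2", "g3"],
                          "r_pooled": [1.0, 0.6, 0.4, -0.7]})
        t.attrs["anchor_gene"] = "anchor"
        return t

    def test_filter_contract(self):
        pos, neg = select_by_threshold(self._table(), 0.5, -0.5)
        assert pos == ["g1"] and neg == ["g3"]

    def test_anchor_never_returned(self):
        pos, neg = select_by_threshold(self._table(), 0.0, 0.0)
        assert "anchor" not in pos and "anchor" not in neg

    def test_boundary_r_min_one(self):
        pos, _ = select_by_threshold(self._table(), 1.0, -1.0)
        assert pos == []

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            select_by_threshold(self._table(), -0.1, -0.5)


class TestTwoSampleTTest:
    def test_identical_groups_give_t_zero_p_one(self):
        t, p = two_sample_ttest([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_large_effect_gives_tiny_p(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 50)
        y = rng.normal(5, 1, 50)
        _, p = two_sample_ttest(x, y)
        assert p < 1e-10

    def test_swapping_groups_negates_t(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 20), rng.normal(1, 2, 25)
        t1, p1 = two_sample_ttest(x, y)
        t2, p2 = two_sample_ttest(y, x)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_welch_default_matches_scipy_pooled_optional(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(0, 1, 12), rng.normal(0.5, 3, 30)
        assert two_sample_ttest(x, y) == pytest.approx(
            tuple(map(float, stats.ttest_ind(x, y, equal_var=False)))
        )
        t_pooled, _ = two_sample_ttest(x, y, equal_var=True)
        assert t_pooled != two_sample_ttest(x, y)[0]

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            two_sample_ttest([1.0], [1, 2, 3])


def _corr_table(rs: dict[str, float]) -> pd.DataFrame:
    return pd.DataFrame({"gene_id": list(rs), "r_pooled": list(rs.values())})


class TestAggregateRanks:
    def test_unanimous_top_gene_ranks_first(self):
        tables = [_corr_table({"a": 0.9, "b": 0.5, "c": 0.1}),
                  _corr_table({"a": 0.8, "b": 0.2, "c": 0.6})]
        out = aggregate_ranks(tables)
        assert out.iloc[0]["gene_id"] == "a" and out.iloc[0]["overall_rank"] == 1

    def test_geometric_mean_of_ranks(self):
        """Ranks (2, 8) across two datasets give score sqrt(16) = 4."""
        t1 = _corr_table({f"g{i}": 1.0 - 0.1 * i for i in range(9)})  # g1 rank 2
        t2 = _corr_table({"g0": 0.9, "g2": 0.8, "g3": 0.7, "g4": 0.6, "g5": 0.5,
                          "g6": 0.4, "g7": 0.3, "g1": 0.15, "g8": 0.1})  # g1 rank 8
        out = aggregate_ranks([t1, t2]).set_index("gene_id")
        assert out.loc["g1", "rank_0"] == 2 and out.loc["g1", "rank_1"] == 8
        assert out.loc["g1", "score"] == pytest.approx(4.0)

    def test_dataset_order_invariance(self):
        rng = np.random.default_rng(8)
        tables = [_corr_table({f"g{i}": float(r) for i, r in enumerate(rng.uniform(-1, 1, 20))})
                  for _ in range(4)]
        a = aggregate_ranks(tables).set_index("gene_id")["score"]
        b = aggregate_ranks(tables[::-1]).set_index("gene_id")["score"]
        pd.testing.assert_series_equal(a, b)

    def test_stable_under_uninformative_dataset_removal(self):
        """Removing a dataset that ranks all genes identically (all tied)
        leaves the top-N ordering unchanged."""
        rng = np.random.default_rng(10)
        informative = [_corr_table({f"g{i}": float(r) for i, r in enumerate(rng.uniform(-1, 1, 15))})
                       for _ in range(3)]
        flat = _corr_table({f"g{i}": 0.5 for i in range(15)})
        with_flat = aggregate_ranks(informative + [flat])
        without = aggregate_ranks(informative)
        assert list(with_flat["gene_id"].head(5)) == list(without["gene_id"].head(5))

    def test_genes_missing_from_one_dataset_dropped(self):
        tables = [_corr_table({"a": 0.9, "b": 0.5, "c": 0.2}),
                  _corr_table({"a": 0.8, "b": 0.3})]
        out = aggregate_ranks(tables)
        assert set(out["gene_id"]) == {"a", "b"}

    def test_empty_intersection_is_hard_error(self):
        with pytest.raises(ValueError, match="shared"):
            aggregate_ranks([_corr_table({"a": 0.1}), _corr_table({"b": 0.1})])

    def test_median_method(self):
        tables = [_corr_table({"a": 0.9, "b": 0.5, "c": 0.1}),
                  _corr_table({"a": 0.1, "b": 0.5, "c": 0.9})]
        out = aggregate_ranks(tables, method="median").set_index("gene_id")
        assert out.loc["b", "score"] == 2.0
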