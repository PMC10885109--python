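import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from clcrep import diversity as dv
from clcrep.errors import ParameterError, UndefinedStatisticError


def gini_bruteforce(counts):
    x = np.asarray(counts, dtype=float)
    n = x.size
    return sum(abs(a - b) for a in x for b in x) / (2 * n * n * x.mean())


class TestGini:
    @pytest.mark.parametrize("counts,expected", [
        ([5, 5, 5, 5], 0.0),
        ([0, 0, 0, 10], 0.75),
        ([1, 2, 3, 4], 0.25),
    ])
    def test_closed_form_examples(self, counts, expected):
        assert dv.gini(counts) == pytest.approx(expected)
        assert dv.gini(counts) == pytest.approx(gini_bruteforce(counts))

    def test_all_zero_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            dv.gini([0, 0, 0])

    @given(st.lists(st.integers(0, 1000), min_size=2, max_size=30).filter(lambda c: sum(c) > 0))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_matches_pairwise_difference_oracle(self, counts):
        assert dv.gini(counts) == pytest.approx(gini_bruteforce(counts))

    @given(
        st.lists(st.integers(0, 500), min_size=2, max_size=20).filter(lambda c: sum(c) > 0),
        st.integers(1, 7),
        st.randoms(use_true_random=False),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_scale_and_permutation_invariance(self, counts, scale, rnd):
        base = dv.gini(counts)
        shuffled = list(counts)
        rnd.shuffle(shuffled)
        assert dv.gini(shuffled) == pytest.approx(base)
        assert dv.gini([c * scale for c in counts]) == pytest.approx(base)
        assert dv.d50([c * scale for c in counts]) == dv.d50(counts)

    def test_one_hot_upper_bound(self):
        for n in (2, 5, 17):
            assert dv.gini([0] * (n - 1) + [9]) == pytest.approx((n - 1) / n)


class TestD50:
    @pytest.mark.parametrize("counts,expected", [
        ([100], 1),
        ([1] * 10, 5),
        ([50, 10, 10, 10, 10, 10], 1),  # largest alone reaches exactly 50%
    ])
    def test_examples(self, counts, expected):
        assert dv.d50(counts) == expected

    def test_cumulative_sum_oracle(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 100, size=40)
        x = np.sort(counts)[::-1]
        k = next(i + 1 for i in range(len(x)) if x[: i + 1].sum() >= 0.5 * x.sum())
        assert dv.d50(counts) == k
        assert dv.d50(counts) <= len(counts)


class TestTopN:
    def test_single_range(self):
        assert dv.topn_fraction([60, 20, 10, 5, 5], [(1, 1)])[(1, 1)] == pytest.approx(0.6)

    def test_uniform_share(self):
        fracs = dv.topn_fraction([10] * 100, [(1, 10)])
        assert fracs[(1, 10)] == pytest.approx(0.10)

    def test_ranks_beyond_categories_contribute_zero(self):
        fracs = dv.topn_fraction([5, 5], [(1, 10), (11, 50)])
        assert fracs[(1, 10)] == pytest.approx(1.0)
        assert fracs[(11, 50)] == 0.0

    def test_overlapping_ranges_rejected(self):
        with pytest.raises(ParameterError):
            dv.topn_fraction([1, 2, 3], [(1, 10), (5, 20)])

    def test_monotone_in_n(self):
        counts = np.random.default_rng(1).integers(1, 50, 30)
        f10 = dv.topn_fraction(counts, [(1, 10)])[(1, 10)]
        f20 = dv.topn_fraction(counts, [(1, 20)])[(1, 20)]
        assert f20 >= f10


class TestDownsample:
    def _cells(self, n=50):
        return pd.DataFrame({"cell_id": [f"c{i}" for i in range(n)],
                             "clonotype_id": ["x"] * n})

    def test_identity_and_determinism(self):
        cells = self._cells()
        full = dv.downsample(cells, 50, seed=1)
        assert sorted(full["cell_id"]) == sorted(cells["cell_id"])
        a = dv.downsample(cells, 20, seed=3)
        b = dv.downsample(cells, 20, seed=3)
        assert a["cell_id"].tolist() == b["cell_id"].tolist()

    def test_clonotype_ids_dropped_for_reassignment(self):
        out = dv.downsample(self._cells(), 10, seed=0)
        assert "clonotype_id" not in out.columns

    def test_oversample_rejected(self):
        with pytest.raises(ParameterError):
            dv.downsample(self._cells(10), 11, seed=0)

    def test_inclusion_frequency_hypergeometric(self):
        cells = self._cells(40)
        n, reps = 10, 400
        hits = np.zeros(40)
        for seed in range(reps):
            idx = dv.downsample(cells, n, seed=seed)["cell_id"]
            hits[[int(c[1:]) for c in idx]] += 1
        p = n / 40
        se = math.sqrt(p * (1 - p) / reps)
        assert np.all(np.abs(hits / reps - p) < 4 * se)


class TestUsage:
    def test_counts_per_gene(self):
        records = pd.DataFrame({
            "locus": ["IGH"] * 5,
            "v_call": ["A", "A", "A", "B", "C"],
            "c_call": ["IGHG1"] * 5,
        })
        counts = dv.usage_table(records, "v_call_heavy")
        assert counts["A"] == 3

    def test_light_field_filters_loci(self):
        records = pd.DataFrame({
            "locus": ["IGH", "IGK", "IGL"],
            "v_call": ["H1", "K1", "L1"],
        })
        counts = dv.usage_table(records, "v_call_light")
        assert set(counts.index) == {"K1", "L1"}

    def test_unknown_field_rejected(self):
        with pytest.raises(ParameterError):
            dv.usage_table(pd.DataFrame({"locus": []}), "nope")


class TestChisq:
    def test_identical_vectors(self):
        a = pd.Series([10, 10], index=["x", "y"])
        statistic, p = dv.compare_usage_chisq(a, a)
        assert statistic == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_textbook_2x2_formula(self):
        a = pd.Series([20, 10], index=["x", "y"])
        b = pd.Series([10, 20], index=["x", "y"])
        statistic, _ = dv.compare_usage_chisq(a, b)
        n, r1, r2, c1, c2 = 60, 30, 30, 30, 30
        expected = n * (20 * 20 - 10 * 10) ** 2 / (r1 * r2 * c1 * c2)
        assert statistic == pytest.approx(expected)

    def test_zero_filling_over_label_union(self):
        a = pd.Series([5], index=["x"])
        b = pd.Series([5], index=["y"])
        statistic, p = dv.compare_usage_chisq(a, b)
        assert statistic == pytest.approx(10.0)  # fully disjoint 2x2

    def test_single_category_rejected(self):
        a = pd.Series([5], index=["x"])
        with pytest.raises(ParameterError):
            dv.compare_usage_chisq(a, a)


def ranksum_exact_p(x, y):
    """Two-sided rank-sum p by enumerating all assignments of ranks."""
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    observed = sum(ranks[v] for v in x)
    nx = len(x)
    sums = [sum(comb) for comb in itertools.combinations(range(1, len(pooled) + 1), nx)]
    mean = np.mean(sums)
    tail = sum(1 for s in sums if abs(s - mean) >= abs(observed - mean) - 1e-9)
    return tail / len(sums)


class TestWilcoxon:
    def test_identical_samples_p_one(self):
        p = dv.wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0, abs=0.05)

    def test_exact_small_sample_matches_enumeration(self):
        x, y = [1, 2, 3], [10, 11, 12]
        assert ranksum_exact_p(x, y) == pytest.approx(0.1)
        assert dv.wilcoxon_rank_sum(x, y) == pytest.approx(0.1)

    def test_degenerate_all_tied_policy(self):
        assert dv.wilcoxon_rank_sum([2, 2], [2, 2, 2]) == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ParameterError):
            dv.wilcoxon_rank_sum([], [1.0])


class TestBenjaminiHochberg:
    def test_equal_pvalues_adjust_by_step_up(self):
        # All m p-values equal: the step-up minimum is p * m / m = p itself.
        adj = dv.benjamini_hochberg([0.005] * 10)
        assert np.allclose(adj, 0.005)

    def test_matches_manual_step_up(self):
        ps = [0.01, 0.04, 0.03, 0.005]
        m = len(ps)
        order = np.argsort(ps)
        sorted_p = np.array(ps)[order]
        manual = np.minimum.accumulate((sorted_p * m / np.arange(1, m + 1))[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(manual, 1.0)
        assert np.allclose(dv.benjamini_hochberg(ps), expected)

    def test_batch_interface(self):
        out = dv.wilcoxon_batch([([1, 2, 3], [10, 11, 12]), ([1, 2], [1, 2])])
        assert out["p_value"].iloc[0] == pytest.approx(0.1)
        assert (out["adjusted_p"] >= out["p_value"] - 1e-12).all()
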