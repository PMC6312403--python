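"""Cohort statistics: summaries, rank-sum, Holm step-down, paired t, blots.

Independent oracles: exhaustive enumeration of rank assignments for the
exact rank-sum p, hand-rolled step-down arithmetic for Holm, and the
closed-form t statistic.
"""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from tirfquant.stats import (
    BlotGrid,
    Cohort,
    compare_cohorts,
    holm_bonferroni,
    normalize_blot,
    paired_t_test,
    rank_sum_test,
    summarize,
)


def exact_rank_sum_p(a, b):
    """Two-sided p by enumerating all C(n_a+n_b, n_a) rank assignments."""
    pooled = np.sort(np.concatenate([a, b]))
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    observed = sum(ranks[v] for v in a)
    n = len(pooled)
    sums = [sum(c) for c in combinations(range(1, n + 1), len(a))]
    mean = len(a) * (n + 1) / 2
    dev = abs(observed - mean)
    extreme = sum(1 for s in sums if abs(s - mean) >= dev - 1e-12)
    return extreme / len(sums)


def holm_oracle(p):
    """Step-down arithmetic, written independently of statsmodels."""
    p = np.asarray(p, dtype=float)
    order = np.argsort(p)
    k = p.size
    adjusted = np.empty(k)
    running = 0.0
    for rank, idx in enumerate(order):
        candidate = min(1.0, (k - rank) * p[idx])
        running = max(running, candidate)
        adjusted[idx] = running
    return adjusted


class TestSummarize:
    def test_constant_cohort(self):
        assert summarize([1.0, 1.0, 1.0]) == pytest.approx((1.0, 0.0, 3))

    def test_sem_uses_sample_sd(self):
        mean, sem, n = summarize([1.0, 2.0, 3.0])
        assert (mean, n) == (2.0, 3)
        assert sem == pytest.approx(1 / np.sqrt(3), abs=1e-12)

    def test_single_value_has_no_sem(self):
        with pytest.raises(ValueError, match="n < 2"):
            summarize([1.0])


class TestRankSum:
    def test_identical_groups_give_p_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        _, p = rank_sum_test(a, a)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_fully_separated_small_samples(self):
        _, p = rank_sum_test([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert p == pytest.approx(0.1, abs=1e-12)
        assert p == pytest.approx(exact_rank_sum_p([1, 2, 3], [4, 5, 6]))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_path_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal(5)
        b = rng.standard_normal(6) + 0.8
        _, p = rank_sum_test(a, b)
        assert p == pytest.approx(exact_rank_sum_p(a, b), abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_exact_and_asymptotic_agree_for_moderate_n(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal(15)
        b = rng.standard_normal(16) + 0.5
        _, p_exact = rank_sum_test(a, b, exact_threshold=20)
        _, p_asym = rank_sum_test(a, b, exact_threshold=0)
        assert abs(p_exact - p_asym) < 0.01

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        a = rng.lognormal(size=12)
        b = rng.lognormal(size=14) * 1.5
        _, p_raw = rank_sum_test(a, b)
        for transform in (np.log, np.sqrt, lambda x: 3 * x + 2, np.exp):
            _, p_t = rank_sum_test(transform(a), transform(b))
            assert p_t == pytest.approx(p_raw, abs=1e-12)

    def test_shifted_cohorts_detected(self):
        # n = 50 per group, one-sd shift: essentially always significant
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = rng.standard_normal(50)
            b = rng.standard_normal(50) + 1.0
            _, p = rank_sum_test(a, b)
            hits += p < 0.01
        assert hits >= 19

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestHolmBonferroni:
    def test_two_p_step_down(self):
        np.testing.assert_allclose(holm_bonferroni([0.01, 0.04]), [0.02, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(holm_bonferroni([0.3]), [0.3])

    def test_monotonicity_enforced(self):
        np.testing.assert_allclose(holm_bonferroni([0.01, 0.011]), [0.02, 0.02])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_bonferroni([0.1, 1.2])

    @given(
        p=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8)
    )
    def test_dominance_and_oracle_agreement(self, p):
        adjusted = holm_bonferroni(p)
        p_arr = np.asarray(p)
        # adjusted >= raw, <= Bonferroni, capped at 1, order-preserving
        assert np.all(adjusted >= p_arr - 1e-15)
        assert np.all(adjusted <= np.minimum(1.0, p_arr * p_arr.size) + 1e-15)
        order = np.argsort(p_arr, kind="stable")
        assert np.all(np.diff(adjusted[order]) >= -1e-15)
        np.testing.assert_allclose(adjusted, holm_oracle(p), atol=1e-12)


class TestPairedT:
    def test_identical_samples_degenerate_null(self):
        assert paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 1.0)

    def test_constant_nonzero_differences_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            paired_t_test([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])

    def test_closed_form_example(self):
        # differences [1, 2, 3]: t = mean/ (sd/sqrt(3)) = 2*sqrt(3), df = 2
        x = np.array([2.0, 4.0, 6.0])
        y = np.array([1.0, 2.0, 3.0])
        t, p = paired_t_test(x, y)
        assert t == pytest.approx(2 * np.sqrt(3), abs=1e-12)
        assert p == pytest.approx(0.0742, abs=5e-4)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0, 2.0], [1.0, 2.0, 3.0])


class TestBlotNormalization:
    def test_all_equal_bands_normalize_to_one(self):
        grid = BlotGrid(
            band_intensities=pd.DataFrame(
                {"phospho": [4.0, 4.0], "pan": [4.0, 4.0]}
            ),
            pan_reference="pan",
        )
        np.testing.assert_allclose(normalize_blot(grid).to_numpy(), 1.0)

    def test_stepwise_arithmetic(self):
        grid = BlotGrid(
            band_intensities=pd.DataFrame(
                {"phospho": [2.0, 4.0], "pan": [3.0, 3.0]}
            ),
            pan_reference="pan",
        )
        out = normalize_blot(grid)
        np.testing.assert_allclose(out["phospho"], [2 / 3, 4 / 3])
        np.testing.assert_allclose(out["pan"], [1.0, 1.0])

    def test_invariant_to_per_blot_exposure(self):
        base = pd.DataFrame({"phospho": [2.0, 5.0, 3.0], "pan": [3.0, 4.0, 2.0]})
        doubled = base.copy()
        doubled["phospho"] *= 2.0  # re-exposing one blot
        a = normalize_blot(BlotGrid(base, "pan"))
        b = normalize_blot(BlotGrid(doubled, "pan"))
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)

    def test_validation(self):
        with pytest.raises(ValueError, match="positive"):
            BlotGrid(pd.DataFrame({"phospho": [0.0], "pan": [1.0]}), "pan")
        with pytest.raises(ValueError, match="missing"):
            BlotGrid(pd.DataFrame({"phospho": [1.0]}), "pan")


class TestCompareCohorts:
    def test_table_and_family_adjustment(self):
        rng = np.random.default_rng(0)
        cohorts = [
            Cohort("control", rng.normal(1.05, 0.1, 40)),
            Cohort("treated", rng.normal(1.5, 0.3, 40)),
            Cohort("vehicle", rng.normal(1.0, 0.05, 20)),
        ]
        family = [("treated", "control"), ("treated", "vehicle"),
                  ("control", "vehicle")]
        summary, comparisons = compare_cohorts(cohorts, family)
        assert list(summary.columns) == ["condition", "mean", "sem", "n"]
        assert summary.loc[summary.condition == "treated", "n"].item() == 40
        assert len(comparisons) == 3
        for c in comparisons:
            assert c.p_adjusted >= c.p_raw - 1e-15

    def test_duplicate_labels_rejected(self):
        c = Cohort("x", np.ones(3))
        with pytest.raises(ValueError, match="unique"):
            compare_cohorts([c, c], [])
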