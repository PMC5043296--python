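import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from oracles import bh_adjust

from allokit.bias import (
    benjamini_hochberg,
    classify_bias,
    compare_rates,
    compute_fpkm,
    filter_min_expression,
    nb_wald_test,
    summarize_bias,
    tissue_percentages,
    window_bias_track,
)
from allokit.bias import test_pair_bias as pair_bias_test


class TestFpkm:
    def test_formula(self):
        counts = pd.DataFrame({"L1": [10, 999_990]}, index=["t1", "t2"])
        lengths = pd.Series({"t1": 1000, "t2": 1000})
        fpkm = compute_fpkm(counts, lengths)
        assert fpkm.loc["t1", "L1"] == pytest.approx(10.0)

    def test_zero_count_zero_fpkm(self):
        counts = pd.DataFrame({"L1": [0, 100]}, index=["t1", "t2"])
        fpkm = compute_fpkm(counts, pd.Series({"t1": 500, "t2": 500}))
        assert fpkm.loc["t1", "L1"] == 0.0

    def test_doubling_library_depth_with_counts_preserves_fpkm(self):
        counts = pd.DataFrame({"L1": [10, 30]}, index=["t1", "t2"])
        doubled = counts * 2
        lengths = pd.Series({"t1": 1000, "t2": 2000})
        assert np.allclose(
            compute_fpkm(counts, lengths), compute_fpkm(doubled, lengths)
        )

    def test_zero_length_rejected(self):
        counts = pd.DataFrame({"L1": [10]}, index=["t1"])
        with pytest.raises(ValueError):
            compute_fpkm(counts, pd.Series({"t1": 0}))


class TestExpressionFilter:
    @pytest.mark.parametrize(
        "values,kept",
        [([0.0, 0.0], False), ([1.0, 0.0], True), ([0.99, 0.5], False)],
    )
    def test_boundaries(self, values, kept):
        fpkm = pd.DataFrame({"L1": [values[0]], "L2": [values[1]]}, index=["t"])
        assert ("t" in filter_min_expression(fpkm)) is kept


class TestWaldTest:
    def test_symmetric_null(self):
        log2_ratio, p = pair_bias_test([100, 100, 100], [100, 100, 100])
        assert log2_ratio == 0.0
        assert p > 0.9

    def test_strong_bias_detected(self):
        log2_ratio, p = pair_bias_test([400, 420, 410], [40, 38, 45])
        assert log2_ratio == pytest.approx(3.3, abs=0.2)
        assert p < 1e-6

    def test_agrees_with_likelihood_ratio_oracle(self):
        # LR test of equal NB means with the dispersion fixed at the same
        # estimate the Wald test uses; both must strongly reject here
        a = np.array([[400, 420, 410]], dtype=float)
        b = np.array([[40, 38, 45]], dtype=float)
        _, p, _ = nb_wald_test(a, b)

        def nb_loglik(x, mu, alpha):
            shape = 1 / alpha
            return stats.nbinom.logpmf(x, shape, shape / (shape + mu)).sum()

        ma, mb = a.mean(), b.mean()
        va, vb = a.var(ddof=1), b.var(ddof=1)
        alpha = max(((va - ma) / ma**2 + (vb - mb) / mb**2) / 2, 0.01)
        pooled = np.concatenate([a[0], b[0]])
        lr = 2 * (
            nb_loglik(a[0], ma, alpha)
            + nb_loglik(b[0], mb, alpha)
            - nb_loglik(pooled, pooled.mean(), alpha)
        )
        p_lr = stats.chi2.sf(lr, df=1)
        assert p[0] < 1e-6 and p_lr < 1e-6

    def test_untestable_all_zero(self):
        _, p, untestable = nb_wald_test(
            np.zeros((1, 3)), np.zeros((1, 3))
        )
        assert untestable[0]
        assert np.isnan(p[0])

    def test_type_one_error_calibrated_under_permuted_null(self):
        rng = np.random.default_rng(12)
        shape = 1 / 0.1
        a = rng.negative_binomial(shape, shape / (shape + 100), size=(2000, 3))
        b = rng.negative_binomial(shape, shape / (shape + 100), size=(2000, 3))
        _, p, _ = nb_wald_test(a, b)
        rate = np.mean(p < 0.05)
        assert 0.03 <= rate <= 0.07


class TestClassification:
    def test_dominance(self):
        category = classify_bias(
            np.nan, np.inf, fpkm_a=np.array([50.0, 55, 45]), fpkm_b=np.zeros(3)
        )
        assert category == "A_dominant"

    def test_not_expressed(self):
        category = classify_bias(
            0.5, 0.0, np.array([0.5, 0.5, 0.5]), np.array([0.5, 0.5, 0.5])
        )
        assert category == "not_expressed"

    def test_nonsignificant_is_balanced(self):
        category = classify_bias(
            0.2, 1.0, np.array([5.0, 5, 5]), np.array([2.0, 2, 2])
        )
        assert category == "balanced"

    def test_significant_direction(self):
        assert (
            classify_bias(0.01, -1.5, np.array([2.0, 2, 2]), np.array([6.0, 6, 6]))
            == "B_biased"
        )


class TestSummaries:
    def test_androecium_row_arithmetic(self):
        # category counts (59, 58, 16, 21, 8161): balanced share of the
        # expressed pairs is 98.1% to one decimal
        pct = tissue_percentages(
            {
                "A_biased": 59,
                "B_biased": 58,
                "A_dominant": 16,
                "B_dominant": 21,
                "balanced": 8161,
            }
        )
        assert round(pct["balanced"], 1) == 98.1

    def test_perianth_bias_share_rounds_to_23(self):
        pct = tissue_percentages(
            {
                "A_biased": 922,
                "B_biased": 934,
                "A_dominant": 41,
                "B_dominant": 49,
                "balanced": 6412,
            }
        )
        biased = sum(pct[c] for c in ("A_biased", "B_biased", "A_dominant",
                                      "B_dominant"))
        assert round(biased) == 23

    def test_no_significant_tests_all_constitutive_balanced(self):
        calls = pd.DataFrame(
            [
                {"pair_id": p, "tissue": t, "category": "balanced"}
                for p in ("p1", "p2", "p3")
                for t in ("t1", "t2")
            ]
        )
        summary = summarize_bias(calls)
        constitutive = summary[summary["tissue"] == "constitutive"].iloc[0]
        assert constitutive["balanced"] == 3
        assert constitutive["A_biased"] == 0

    def test_constitutive_requires_same_direction_everywhere(self):
        rows = []
        # p1: A-biased in both expressed tissues -> constitutive
        # p2: biased in one, balanced in the other -> not constitutive
        # p3: expressed in one tissue only -> not constitutive (needs >= 2)
        for tissue, cats in (
            ("t1", {"p1": "A_biased", "p2": "A_biased", "p3": "A_biased"}),
            ("t2", {"p1": "A_dominant", "p2": "balanced", "p3": "not_expressed"}),
        ):
            for pair, cat in cats.items():
                rows.append({"pair_id": pair, "tissue": tissue, "category": cat})
        summary = summarize_bias(pd.DataFrame(rows))
        constitutive = summary[summary["tissue"] == "constitutive"].iloc[0]
        assert constitutive["A_biased"] == 1

    def test_category_counts_sum_to_expressed_pairs(self, dataset):
        from allokit.bias import run_bias_analysis
        from allokit.pairing import HomeologPair

        pairs = [HomeologPair(a, b, 1.0, 1.0) for a, b in dataset.truth.pairs]
        _, calls = run_bias_analysis(
            dataset.counts, dataset.lengths, dataset.sheet, pairs
        )
        assert len(calls) == len(pairs) * len(dataset.sheet.tissues)
        summary = summarize_bias(calls)
        tissue_rows = summary[summary["tissue"] != "constitutive"]
        for _, row in tissue_rows.iterrows():
            total = sum(
                row[c]
                for c in ("A_biased", "B_biased", "A_dominant", "B_dominant",
                          "balanced")
            )
            assert total == row["expressed_pairs"]


class TestWindows:
    def _loci(self, n):
        return pd.DataFrame(
            {
                "pair_id": [f"p{i}" for i in range(n)],
                "chromosome_pair": "c1",
                "position": range(n),
            }
        )

    def _calls(self, n, category="balanced"):
        return pd.DataFrame(
            {
                "pair_id": [f"p{i}" for i in range(n)],
                "tissue": "leaf",
                "category": category,
            }
        )

    def test_120_loci_give_8_windows(self):
        tracks = window_bias_track(self._loci(120), self._calls(120), "leaf")
        assert [t.window_start for t in tracks] == list(range(0, 80, 10))

    def test_all_balanced_zero_fractions(self):
        tracks = window_bias_track(self._loci(60), self._calls(60), "leaf")
        assert all(t.frac_a_biased == 0 and t.frac_b_biased == 0 for t in tracks)

    def test_50_loci_all_a_biased_single_full_window(self):
        tracks = window_bias_track(
            self._loci(50), self._calls(50, "A_biased"), "leaf"
        )
        assert len(tracks) == 1
        assert tracks[0].frac_a_biased == 1.0

    def test_fewer_than_window_single_whole_chromosome_window(self):
        tracks = window_bias_track(self._loci(30), self._calls(30), "leaf")
        assert len(tracks) == 1
        assert tracks[0].n_loci == 30


class TestMultipleTesting:
    def test_hand_bh_example(self):
        assert np.allclose(
            benjamini_hochberg(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03]
        )

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=10)
    )
    def test_matches_hand_bh_on_short_lists(self, pvalues):
        got = benjamini_hochberg(np.array(pvalues))
        want = bh_adjust(pvalues)
        assert np.allclose(got, want)
        order = np.argsort(pvalues)
        assert (np.diff(got[order]) >= -1e-12).all()


class TestRankSum:
    def test_exact_small_sample(self):
        assert compare_rates([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_groups(self):
        assert compare_rates([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(13)
        unbiased = rng.uniform(0, 0.05, size=500)
        biased = rng.uniform(0.01, 0.06, size=500)
        assert compare_rates(list(biased), list(unbiased)) < 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_rates([], [1.0])
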