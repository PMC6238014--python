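from itertools import combinations
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import datpipe as dp


class TestGlassDelta:
    def test_published_summary_values(self):
        assert round(dp.glass_delta_from_summary(2.80, 1.77, 0.45), 2) == 2.29
        assert round(dp.glass_delta_from_summary(6.21, 4.26, 0.76), 2) == 2.57

    def test_identical_groups_give_zero(self):
        x = [1.0, 2.0, 3.0]
        assert dp.glass_delta(x, x) == 0.0

    def test_sample_sd_uses_n_minus_1(self):
        hc = np.array([1.0, 3.0])  # mean 2, sample SD sqrt(2)
        assert dp.glass_delta(hc, [0.0]) == pytest.approx(2.0 / np.sqrt(2.0))

    def test_zero_control_variance_flagged(self):
        with pytest.raises(ValueError, match="undefined"):
            dp.glass_delta([2.0, 2.0], [1.0])

    @settings(derandomize=True, max_examples=30)
    @given(
        a=st.floats(min_value=0.1, max_value=50),
        b=st.floats(min_value=-100, max_value=100),
    )
    def test_invariant_under_common_affine_rescaling(self, a, b):
        rng = np.random.default_rng(0)
        hc = rng.normal(3.0, 0.5, 15)
        ps = rng.normal(2.0, 1.0, 12)
        base = dp.glass_delta(hc, ps)
        scaled = dp.glass_delta(a * hc + b, a * ps + b)
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-9)


class TestIccConsistency:
    def test_perfect_agreement(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert dp.icc_consistency(x, x) == pytest.approx(1.0)

    def test_additive_offset_ignored(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert dp.icc_consistency(x, x + 3.7) == pytest.approx(1.0)

    def test_matches_explicit_anova_table(self):
        """Brute-force two-way ANOVA sum-of-squares arithmetic on a toy set."""
        x = np.array([7.0, 9.0, 10.0, 6.0, 8.0])
        y = np.array([8.0, 11.0, 9.0, 7.0, 10.0])
        n, k = 5, 2
        data = np.column_stack([x, y])
        grand = data.mean()
        ss_subj = k * ((data.mean(axis=1) - grand) ** 2).sum()
        ss_meth = n * ((data.mean(axis=0) - grand) ** 2).sum()
        ss_err = ((data - grand) ** 2).sum() - ss_subj - ss_meth
        msr, mse = ss_subj / (n - 1), ss_err / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + mse)
        assert dp.icc_consistency(x, y) == pytest.approx(expected, rel=1e-12)

    def test_matches_pingouin_icc3(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(42)
        x = rng.normal(3, 1, 20)
        y = 0.9 * x + rng.normal(0, 0.3, 20) + 0.5
        df = pd.DataFrame(
            {
                "subject": np.tile(np.arange(20), 2),
                "rater": np.repeat(["a", "b"], 20),
                "score": np.concatenate([x, y]),
            }
        )
        table = pingouin.intraclass_corr(
            df, targets="subject", raters="rater", ratings="score"
        )
        # single-rater consistency ICC; the label differs across versions
        row = table[table["Type"].isin(["ICC3", "ICC(C,1)"])]
        assert dp.icc_consistency(x, y) == pytest.approx(
            float(row["ICC"].iloc[0]), rel=1e-9
        )

    def test_noise_reduces_expected_consistency(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 200)
        noisy = dp.icc_consistency(x, x + rng.normal(0, 0.8, 200))
        assert noisy < 1.0

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            dp.icc_consistency([1.0, 2.0], [1.0, 2.0])

    def test_zero_between_subject_variance_rejected(self):
        with pytest.raises(ValueError):
            dp.icc_consistency([2.0, 2.0, 2.0], [3.0, 3.0, 3.0])


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = dp.roc_auc([0, 0, 1, 1], [1.0, 2.0, 5.0, 6.0], ci=False)
        assert auc == 1.0

    def test_all_ties_give_half(self):
        auc, _ = dp.roc_auc([0, 0, 1, 1], [3.0, 3.0, 3.0, 3.0], ci=False)
        assert auc == 0.5

    def test_direction_lower_flips(self):
        auc, _ = dp.roc_auc([0, 0, 1, 1], [5.0, 6.0, 1.0, 2.0], direction="lower", ci=False)
        assert auc == 1.0

    def test_matches_bruteforce_pair_counting(self, rng):
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]  # both classes present
        scores = np.round(rng.normal(0, 1, 40), 1)  # rounding creates ties
        auc, _ = dp.roc_auc(labels, scores, ci=False)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert auc == pytest.approx(wins / (pos.size * neg.size), rel=1e-12)

    def test_matches_sklearn(self, rng):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        labels = np.array([0] * 15 + [1] * 10)
        scores = rng.normal(labels, 1.0)
        auc, _ = dp.roc_auc(labels, scores, ci=False)
        assert auc == pytest.approx(sklearn_metrics.roc_auc_score(labels, scores))

    def test_bootstrap_ci_brackets_point_estimate(self, rng):
        labels = np.array([0] * 15 + [1] * 15)
        scores = rng.normal(labels * 1.5, 1.0)
        auc, (lo, hi) = dp.roc_auc(labels, scores, seed=1)
        assert lo <= auc <= hi
        assert 0.0 <= lo < hi <= 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            dp.roc_auc([1, 1], [0.5, 0.6])


class TestMannWhitneyExact:
    def test_smallest_attainable_two_sided_p_for_2v2(self):
        assert dp.mann_whitney_exact([1.0, 2.0], [3.0, 4.0]) == pytest.approx(1 / 3)

    def test_identical_groups_give_one(self):
        assert dp.mann_whitney_exact([5.0, 5.0], [5.0, 5.0, 5.0]) == 1.0

    def test_matches_enumeration_oracle(self, rng):
        """Independent enumeration over all group assignments, n1+n2 <= 12."""
        from scipy.stats import rankdata

        x = rng.normal(0, 1, 5)
        y = rng.normal(0.8, 1, 6)
        pooled = np.concatenate([x, y])
        ranks = rankdata(pooled)
        offset = x.size * (x.size + 1) / 2
        u_obs = ranks[: x.size].sum() - offset
        us = [
            ranks[list(idx)].sum() - offset
            for idx in combinations(range(pooled.size), x.size)
        ]
        us = np.array(us)
        expected = min(1.0, 2 * min((us <= u_obs + 1e-9).mean(), (us >= u_obs - 1e-9).mean()))
        assert dp.mann_whitney_exact(x, y) == pytest.approx(expected, rel=1e-12)

    def test_matches_scipy_exact_without_ties(self, rng):
        from scipy.stats import mannwhitneyu

        x = rng.normal(0, 1, 6)
        y = rng.normal(1, 1, 7)
        expected = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert dp.mann_whitney_exact(x, y) == pytest.approx(expected, rel=1e-9)

    def test_monte_carlo_close_to_enumeration(self, rng):
        x = rng.normal(0, 1, 8)
        y = rng.normal(0.5, 1, 8)
        exact = dp.mann_whitney_exact(x, y)
        mc = dp.mann_whitney_exact(x, y, max_enumeration=10, n_mc=40_000, seed=5)
        assert mc == pytest.approx(exact, abs=0.02)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            dp.mann_whitney_exact([], [1.0])


class TestCorrelations:
    def test_perfect_positive_and_negative(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert dp.correlations(a, a)[0] == pytest.approx(1.0)
        assert dp.correlations(a, -a)[0] == pytest.approx(-1.0)

    def test_monotone_nonlinear_spearman_one_pearson_below(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.exp(a)
        assert dp.correlations(a, b, "spearman")[0] == pytest.approx(1.0)
        assert dp.correlations(a, b, "pearson")[0] < 1.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            dp.correlations([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestLaterality:
    def test_lr_average(self):
        assert dp.lr_average(2.0, 4.0) == 3.0
        assert dp.lr_average(5.0, 5.0) == 5.0
        with pytest.raises(ValueError):
            dp.lr_average(np.nan, 1.0)

    def test_contralateral_selection(self):
        assert dp.contralateral_select(1.5, 2.5, "right") == 1.5
        assert dp.contralateral_select(1.5, 2.5, "left") == 2.5
        assert dp.contralateral_select(1.5, 2.5, "symmetric") == 1.5
        with pytest.raises(ValueError):
            dp.contralateral_select(1.0, 2.0, "none")

    def test_concordance_counts(self):
        # 20 lateralized patients, 18 with the lower value contralateral
        sides = ["right"] * 10 + ["left"] * 10
        left = np.array([1.0] * 10 + [2.0] * 8 + [1.0] * 2)
        right = np.array([2.0] * 10 + [1.0] * 8 + [2.0] * 2)
        assert dp.laterality_concordance(left, right, sides) == pytest.approx(90.0)

    def test_all_concordant(self):
        assert dp.laterality_concordance([1.0], [2.0], ["right"]) == 100.0

    def test_no_lateralized_patients_rejected(self):
        with pytest.raises(ValueError):
            dp.laterality_concordance([1.0], [2.0], ["symmetric"])


class TestResidualize:
    def test_removes_linear_trend(self, rng):
        age = rng.uniform(50, 80, 30)
        values = 5.0 - 0.04 * age + rng.normal(0, 0.1, 30)
        resid = dp.residualize(values, age)
        assert abs(np.corrcoef(resid, age)[0, 1]) < 1e-10
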