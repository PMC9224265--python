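"""Diagnostic statistics: ROC, DeLong, Youden, Wilson, MWU, chi-square, LR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fetpet import (
    compare_roc,
    cutoff_ci,
    empirical_roc,
    fit_logistic,
    generate_cohort,
    mwu_test,
    proportion_test,
    reference_cohort,
    summarize_cohort,
    wilson_ci,
    youden_optimum,
)
from conftest import bruteforce_auc, bruteforce_youden, enumerate_mwu_p


def random_cohort(rng, n_max=30):
    """Random values/labels with both classes present and occasional ties."""
    n = int(rng.integers(4, n_max + 1))
    values = np.round(rng.normal(0, 1, n), 1)  # rounding creates ties
    labels = np.zeros(n, bool)
    n_pos = int(rng.integers(1, n))
    labels[rng.choice(n, n_pos, replace=False)] = True
    return values, labels


class TestEmpiricalRoc:
    def test_perfect_separation(self):
        r = empirical_roc([1, 2, 3, 4], ["TRC", "TRC", "TP", "TP"])
        assert r.auc == 1.0

    def test_all_ties(self):
        r = empirical_roc([2, 2, 2, 2], ["TRC", "TP", "TRC", "TP"])
        assert r.auc == 0.5

    def test_interleaved(self):
        # 4 TP-TRC pairs: 3 concordant, 1 tie-free discordant -> 0.75
        r = empirical_roc([1, 2, 3, 4], ["TRC", "TP", "TRC", "TP"])
        assert r.auc == 0.75

    def test_points_monotone_and_anchored(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            v, y = random_cohort(rng)
            r = empirical_roc(v, y)
            assert r.fpr[0] == r.tpr[0] == 0.0
            assert r.fpr[-1] == r.tpr[-1] == 1.0
            assert np.all(np.diff(r.fpr) >= 0) and np.all(np.diff(r.tpr) >= 0)

    def test_auc_equals_trapezoid_and_pair_counting(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            v, y = random_cohort(rng)
            r = empirical_roc(v, y)
            assert r.auc == pytest.approx(bruteforce_auc(v, y), abs=1e-12)
            assert r.auc == pytest.approx(np.trapezoid(r.tpr, r.fpr), abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        for _ in range(10):
            v, y = random_cohort(rng)
            assert empirical_roc(v, y).auc == pytest.approx(roc_auc_score(y, v))

    def test_lower_orientation_flips(self):
        v = [1.0, 2.0, 3.0, 4.0]
        y = ["TP", "TP", "TRC", "TRC"]
        assert empirical_roc(v, y, "higher").auc == 0.0
        assert empirical_roc(v, y, "lower").auc == 1.0

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            empirical_roc([1, 2], ["TP", "TP"])

    def test_delong_sd_close_to_bootstrap_sd(self):
        rng = np.random.default_rng(4)
        n = 200
        v = np.concatenate([rng.normal(1, 1, n), rng.normal(0, 1, n)])
        y = np.concatenate([np.ones(n, bool), np.zeros(n, bool)])
        r = empirical_roc(v, y)
        aucs = np.empty(2000)
        pos, neg = v[y], v[~y]
        for b in range(2000):
            pb = rng.choice(pos, n)
            nb = rng.choice(neg, n)
            ranks = sps.rankdata(np.concatenate([pb, nb]))
            aucs[b] = (ranks[:n].sum() - n * (n + 1) / 2) / (n * n)
        boot_sd = aucs.std(ddof=1)
        assert abs(r.auc_sd - boot_sd) / boot_sd < 0.15


class TestCompareRoc:
    def test_self_comparison_p_one(self):
        a = ([1, 2, 3, 4], ["TRC", "TRC", "TP", "TP"])
        assert compare_roc(a, a, paired=True) == 1.0

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        y = rng.random(60) < 0.5
        y[:2] = [True, False]
        a = (rng.normal(y.astype(float), 1), y)
        b = (rng.normal(0, 1, 60), y)
        assert compare_roc(a, b) == pytest.approx(compare_roc(b, a))

    def test_separating_vs_noise_significant(self):
        rng = np.random.default_rng(6)
        n = 200
        y = np.concatenate([np.ones(n, bool), np.zeros(n, bool)])
        strong = np.concatenate([np.ones(n), np.zeros(n)])  # perfect marker
        noise = rng.normal(0, 1, 2 * n)
        assert compare_roc((strong, y), (noise, y), paired=True) < 0.01

    def test_agrees_with_permutation_oracle(self):
        # moderate effect so the p-value sits away from 0 and 1
        rng = np.random.default_rng(7)
        n = 80
        y = np.concatenate([np.ones(n, bool), np.zeros(n, bool)])
        a_vals = np.concatenate([rng.normal(0.5, 1, n), rng.normal(0, 1, n)])
        b_vals = rng.normal(0, 1, 2 * n)
        p_delong = compare_roc((a_vals, y), (b_vals, y), paired=True)

        def auc(v, lab):
            ranks = sps.rankdata(v)
            n1 = lab.sum()
            return (ranks[lab].sum() - n1 * (n1 + 1) / 2) / (n1 * (lab.size - n1))

        obs = abs(auc(a_vals, y) - auc(b_vals, y))
        count = 0
        n_perm = 2000
        for _ in range(n_perm):
            swap = rng.random(2 * n) < 0.5  # paired: swap markers within patient
            av = np.where(swap, b_vals, a_vals)
            bv = np.where(swap, a_vals, b_vals)
            if abs(auc(av, y) - auc(bv, y)) >= obs - 1e-12:
                count += 1
        p_perm = count / n_perm
        assert abs(p_delong - p_perm) < 0.05

    def test_unpaired_mode_and_length_check(self):
        a = ([1, 2, 3, 4], ["TRC", "TRC", "TP", "TP"])
        b = ([1, 2, 3], ["TRC", "TP", "TP"])
        with pytest.raises(ValueError):
            compare_roc(a, b, paired=True)
        assert 0 <= compare_roc(a, b, paired=False) <= 1


class TestYoudenOptimum:
    def test_perfectly_separated(self):
        c = youden_optimum([1, 2, 5, 6], ["TRC", "TRC", "TP", "TP"])
        assert c.youden_j == 1.0
        assert 2 < c.threshold < 5

    def test_worked_example(self):
        c = youden_optimum([1, 2, 2, 2, 3, 3], ["TRC", "TRC", "TRC", "TP", "TP", "TP"])
        assert c.threshold == 2.5
        assert c.youden_j == pytest.approx(2 / 3)

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            v, y = random_cohort(rng)
            got = youden_optimum(v, y)
            thr, j = bruteforce_youden(v, y)
            assert got.threshold == pytest.approx(thr)
            assert got.youden_j == pytest.approx(j)

    def test_orientation_coherence(self):
        rng = np.random.default_rng(9)
        v, y = random_cohort(rng)
        hi = youden_optimum(v, y, "higher")
        lo = youden_optimum(-v, y, "lower")
        assert lo.threshold == pytest.approx(-hi.threshold)
        assert lo.youden_j == pytest.approx(hi.youden_j)
        assert lo.sensitivity.estimate == hi.sensitivity.estimate
        assert lo.specificity.estimate == hi.specificity.estimate

    def test_accuracy_is_correct_call_fraction(self):
        rng = np.random.default_rng(10)
        v, y = random_cohort(rng)
        c = youden_optimum(v, y)
        pred = v >= c.threshold
        assert c.accuracy.estimate == pytest.approx((pred == y).mean())

    def test_ci_attached_when_requested(self):
        v = np.concatenate([np.full(10, 1.0) + np.arange(10) * 0.01, np.full(10, 5.0)])
        y = np.array([False] * 10 + [True] * 10)
        c = youden_optimum(v, y, n_boot=200, seed=0)
        lo, hi = c.threshold_ci95
        assert lo <= c.threshold <= hi


class TestCutoffCi:
    def test_seeded_determinism(self):
        rng = np.random.default_rng(11)
        v, y = random_cohort(rng, 25)
        assert cutoff_ci(v, y, n_boot=200, seed=4) == cutoff_ci(v, y, n_boot=200, seed=4)

    def test_separated_classes_ci_inside_gap(self):
        # TRC tightly around 1, TP tightly around 5: every resample puts the
        # cutoff in the gap, so the CI is narrower than the gap itself
        rng = np.random.default_rng(12)
        v = np.concatenate([rng.normal(1, 0.05, 30), rng.normal(5, 0.05, 30)])
        y = np.array([False] * 30 + [True] * 30)
        lo, hi = cutoff_ci(v, y, n_boot=300, seed=1)
        assert 1.5 < lo <= hi < 4.5

    def test_bootstrap_ci_covers_generative_optimum(self):
        # two normal classes: the population Youden threshold is where the
        # densities cross (equal variances -> midpoint of the means)
        mu_trc, mu_tp, sd = 2.0, 4.0, 1.0
        t_star = (mu_trc + mu_tp) / 2
        rng = np.random.default_rng(13)
        n = 200
        covered = 0
        for rep in range(100):
            v = np.concatenate([rng.normal(mu_tp, sd, n), rng.normal(mu_trc, sd, n)])
            y = np.array([True] * n + [False] * n)
            lo, hi = cutoff_ci(v, y, n_boot=300, seed=1000 + rep)
            covered += lo <= t_star <= hi
        assert covered >= 90


class TestWilsonCi:
    @pytest.mark.parametrize(
        "s,n,lo_pct,hi_pct",
        [(24, 31, 60, 89), (10, 11, 62, 98), (11, 11, 74, 100), (16, 17, 73, 99)],
    )
    def test_reference_cells(self, s, n, lo_pct, hi_pct):
        lo, hi = wilson_ci(s, n)
        assert round(lo * 100) == lo_pct
        assert round(hi * 100) == hi_pct

    def test_zero_successes_clipped(self):
        lo, hi = wilson_ci(0, 10)
        assert lo == 0.0 and 0 < hi < 1

    def test_contains_point_estimate(self):
        for s, n in [(1, 10), (5, 9), (9, 9), (40, 123)]:
            lo, hi = wilson_ci(s, n)
            assert lo <= s / n <= hi

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            wilson_ci(5, 4)
        with pytest.raises(ValueError):
            wilson_ci(-1, 4)


class TestMwu:
    def test_small_sample_exact(self):
        u, p, method = mwu_test([1, 2], [3, 4])
        assert u == 0.0 and p == pytest.approx(1 / 3) and method == "exact"

    def test_identical_samples(self):
        _, p, _ = mwu_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_exact_matches_enumeration(self):
        rng = np.random.default_rng(14)
        for _ in range(10):
            m, n = rng.integers(2, 9, 2)
            vals = rng.permutation(np.arange(1.0, m + n + 1))  # untied
            x, y = vals[:m], vals[m:]
            _, p, method = mwu_test(x, y)
            assert method == "exact"
            assert p == pytest.approx(enumerate_mwu_p(x, y), abs=1e-12)

    def test_asymptotic_close_to_exact_at_n8(self):
        rng = np.random.default_rng(15)
        x = rng.normal(0, 1, 8)
        y = rng.normal(0.8, 1, 8)
        _, p_exact, _ = mwu_test(list(x), list(y))
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                               use_continuity=True)
        assert abs(p_exact - res.pvalue) < 0.02

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            mwu_test([], [1.0])


class TestProportionTest:
    def test_no_association(self):
        stat, p, _ = proportion_test([[10, 10], [10, 10]])
        assert stat == 0.0 and p == 1.0

    def test_reference_counts(self):
        # TRC/TP split by IDH group: essentially no association
        stat, p, _ = proportion_test([[5, 13], [7, 19]])
        assert stat == pytest.approx(0.004, abs=0.001)
        assert p == pytest.approx(0.95, abs=0.005)

    def test_fisher_extreme_table(self):
        _, p, _ = proportion_test([[10, 0], [0, 10]], method="fisher")
        assert p < 0.001
        # hypergeometric enumeration: both one-sided tails are a single table
        expected = 2 * sps.hypergeom.pmf(10, 20, 10, 10)
        assert p == pytest.approx(expected)

    def test_degenerate_margin_raises(self):
        with pytest.raises(ValueError):
            proportion_test([[0, 0], [3, 4]])


class TestFitLogistic:
    def test_intercept_only_predicts_prevalence(self):
        co = generate_cohort(n_per_group=25, seed=16)
        fit = fit_logistic(co, ())
        prev = (co["outcome"] == "TP").mean()
        assert np.allclose(fit.predicted_prob, prev, atol=1e-8)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(17)
        n = 5000
        x = rng.normal(2.0, 0.75, n)
        p = 1 / (1 + np.exp(-(-3.0 + 1.6 * x)))
        df = pd.DataFrame(
            {
                "outcome": np.where(rng.random(n) < p, "TP", "TRC"),
                "tbr_mean": x,
                "idh": "mutant",
                "tac_score": 0,
            }
        )
        fit = fit_logistic(df, ("tbr_mean",))
        assert fit.converged and not fit.separation_flag
        se_int = (fit.conf_int["intercept"][1] - fit.conf_int["intercept"][0]) / (2 * 1.96)
        se_slope = (fit.conf_int["tbr_mean"][1] - fit.conf_int["tbr_mean"][0]) / (2 * 1.96)
        assert abs(fit.params["intercept"] - (-3.0)) < 2 * se_int
        assert abs(fit.params["tbr_mean"] - 1.6) < 2 * se_slope
        assert fit.odds_ratios["tbr_mean"][0] == pytest.approx(np.exp(fit.params["tbr_mean"]))

    def test_separation_flagged(self):
        df = pd.DataFrame(
            {
                "outcome": ["TP"] * 5 + ["TRC"] * 5,
                "tbr_mean": [3.0, 3.1, 3.2, 3.3, 3.4, 1.0, 1.1, 1.2, 1.3, 1.4],
            }
        )
        fit = fit_logistic(df, ("tbr_mean",))
        assert fit.separation_flag and not fit.converged

    def test_collinear_design_raises(self):
        co = generate_cohort(n_per_group=10, seed=18)
        co["tbr_max"] = 2.0 * co["tbr_mean"]
        with pytest.raises(ValueError, match="collinear"):
            fit_logistic(co, ("tbr_mean", "tbr_max"))

    def test_constant_outcome_raises(self):
        co = generate_cohort(n_per_group=10, seed=19)
        co["outcome"] = "TP"
        with pytest.raises(ValueError):
            fit_logistic(co, ("tbr_mean",))


class TestSummarizeCohort:
    def test_reference_proportions(self):
        ref = reference_cohort()
        all_block = summarize_cohort(ref, "all", n_boot=100, seed=0)
        assert all_block["proportions"]["tp_pct"] == pytest.approx(100 * 32 / 44)
        wt = summarize_cohort(ref, "IDHwt", n_boot=100, seed=0)
        assert wt["proportions"]["trc_pct"] == pytest.approx(100 * 5 / 18)

    def test_degenerate_stratum_omits_diagnostics(self, caplog):
        co = generate_cohort(n_per_group=15, seed=20)
        co.loc[co["idh"] == "wildtype", "outcome"] = "TP"
        block = summarize_cohort(co, "IDHwt", n_boot=100, seed=0)
        assert block["variables"] == {}
        assert block["warnings"]

    def test_listwise_missing_exclusion_logged(self):
        co = generate_cohort(n_per_group=15, seed=21)
        co.loc[co.index[:3], "ttp_min"] = np.nan
        block = summarize_cohort(co, "all", n_boot=100, seed=0)
        assert block["variables"]["ttp_min"]["by_outcome"]["TP"]["n"] + \
            block["variables"]["ttp_min"]["by_outcome"]["TRC"]["n"] == len(co) - 3
        assert any("excluded listwise" in w for w in block["warnings"])

    def test_ttp_uses_lower_orientation(self):
        co = generate_cohort(n_per_group=40, seed=22)
        block = summarize_cohort(co, "all", n_boot=100, seed=0)
        v = block["variables"]["ttp_min"]
        assert v["orientation"] == "lower"
        # TP is generated with earlier peaks, so "lower indicates TP" should
        # put the AUC above one half
        assert v["auc"] > 0.5
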