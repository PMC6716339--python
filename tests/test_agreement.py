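"""The method-comparison battery: correlations, ICC, MAPE, Bland-Altman."""
import numpy as np
import pandas as pd
import pytest

from wearval.agreement import (
    PairedOutcomes,
    UndefinedStatisticError,
    bland_altman,
    compare,
    goal_sens_spec,
    icc_agreement,
    interpret_icc,
    interpret_pearson,
    mape,
    pearson_bootstrap,
    spearman_rho,
)


def pairs(test, criterion, name="x"):
    return PairedOutcomes(name, np.asarray(test, float), np.asarray(criterion, float),
                          [f"S{i}" for i in range(len(test))])


class TestPearsonBootstrap:
    def test_identity_gives_r_one(self):
        r, ci = pearson_bootstrap(pairs([1, 2, 3, 4], [1, 2, 3, 4]), seed=0)
        assert r == pytest.approx(1.0)

    def test_negation_gives_r_minus_one(self):
        r, _ = pearson_bootstrap(pairs([1, 2, 3], [3, 2, 1]), seed=0)
        assert r == pytest.approx(-1.0)

    def test_closed_form_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 4.0, 5.0, 9.0])
        # independent closed form: cov(x,y)/(sd_x sd_y)
        expect = (((x - x.mean()) * (y - y.mean())).sum()
                  / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        r, _ = pearson_bootstrap(pairs(x, y), seed=0)
        assert r == pytest.approx(expect, abs=1e-12)

    def test_constant_vector_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            pearson_bootstrap(pairs([1, 1, 1], [1, 2, 3]), seed=0)

    def test_reproducible_given_seed(self):
        p = pairs(np.arange(10), np.arange(10) ** 1.3)
        assert pearson_bootstrap(p, seed=4) == pearson_bootstrap(p, seed=4)

    def test_ci_contains_point_estimate_in_nearly_all_seeded_runs(self):
        rng = np.random.default_rng(123)
        x = rng.normal(100, 15, 25)
        y = x + rng.normal(0, 10, 25)
        p = pairs(x, y)
        hits = 0
        for seed in range(100):
            r, (lo, hi) = pearson_bootstrap(p, n_boot=200, seed=seed)
            hits += lo <= r <= hi
        assert hits >= 99

    def test_incomplete_pairs_dropped(self):
        p = PairedOutcomes("x", [1, 2, np.nan, 4], [1, 2, 3, np.nan],
                           ["a", "b", "c", "d"])
        assert p.n == 2 and p.subject_ids == ["a", "b"]


class TestIcc:
    def test_identical_instruments(self):
        icc, ci = icc_agreement(pairs([3, 7, 9, 12], [3, 7, 9, 12]))
        assert icc == 1.0 and ci == (1.0, 1.0)

    def test_offset_penalised_below_pearson(self):
        x = np.array([10, 20, 30, 40, 50.0])
        p = pairs(x + 15, x)
        icc, _ = icc_agreement(p)
        r, _ = pearson_bootstrap(p, seed=0)
        assert icc < r  # absolute agreement punishes the constant bias

    def test_six_subject_hand_anova_oracle(self):
        """Independent oracle: explicit two-way ANOVA mean-squares
        decomposition computed step by step on a 6-subject table."""
        t = np.array([166.0, 355.0, 435.0, 530.0, 289.0, 120.0])
        c = np.array([150.0, 330.0, 460.0, 500.0, 310.0, 140.0])
        x = np.column_stack([t, c])
        n, k = x.shape
        grand = x.mean()
        msr = k * ((x.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((x.mean(0) - grand) ** 2).sum() / (k - 1)
        sse = ((x - grand) ** 2).sum() - k * ((x.mean(1) - grand) ** 2).sum() \
            - n * ((x.mean(0) - grand) ** 2).sum()
        mse = sse / ((n - 1) * (k - 1))
        expect = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        icc, ci = icc_agreement(pairs(t, c))
        assert icc == pytest.approx(expect, abs=1e-12)
        assert ci[0] <= icc <= ci[1]

    def test_matches_pingouin_cross_check(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        c = rng.normal(100, 20, 18)
        t = 0.9 * c + rng.normal(0, 8, 18) + 5
        icc, ci = icc_agreement(pairs(t, c))
        long = pd.DataFrame({
            "subject": list(range(18)) * 2, "rater": ["t"] * 18 + ["c"] * 18,
            "score": np.concatenate([t, c])})
        row = pg.intraclass_corr(long, targets="subject", raters="rater",
                                 ratings="score").set_index("Type").loc["ICC(A,1)"]
        assert icc == pytest.approx(float(row["ICC"]), abs=1e-10)
        assert ci[0] == pytest.approx(row["CI95"][0], abs=0.011)  # pingouin rounds
        assert ci[1] == pytest.approx(row["CI95"][1], abs=0.011)

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            icc_agreement(pairs([5, 5, 5], [5, 5, 5]))


class TestMape:
    def test_perfect_agreement_is_zero(self):
        assert mape(pairs([10, 20], [10, 20])) == 0.0

    def test_direct_arithmetic_example(self):
        assert mape(pairs([110, 180], [100, 200])) == pytest.approx(10.0)

    def test_elementwise_oracle_and_scale_invariance(self):
        rng = np.random.default_rng(1)
        c = rng.uniform(50, 500, 30)
        t = c * rng.uniform(0.7, 1.3, 30)
        expect = np.mean(np.abs(t - c) / c) * 100
        assert mape(pairs(t, c)) == pytest.approx(expect, abs=1e-12)
        assert mape(pairs(3.5 * t, 3.5 * c)) == pytest.approx(expect, abs=1e-9)

    def test_zero_criteria_dropped_or_undefined(self):
        assert mape(pairs([10, 99], [10, 0])) == 0.0  # zero pair dropped
        with pytest.raises(UndefinedStatisticError):
            mape(pairs([1, 2], [0, 0]))


class TestBlandAltman:
    def test_identical_vectors(self):
        ba = bland_altman(pairs([1, 2, 3], [1, 2, 3]))
        assert ba.mean_diff == 0 and ba.lower_loa == 0 and ba.upper_loa == 0

    def test_constant_offset(self):
        ba = bland_altman(pairs([51, 52, 53], [1, 2, 3]))
        assert ba.mean_diff == pytest.approx(50)
        assert ba.lower_loa == pytest.approx(50)
        assert ba.upper_loa == pytest.approx(50)

    def test_elementwise_oracle(self):
        rng = np.random.default_rng(8)
        c = rng.normal(500, 100, 40)
        t = c + rng.normal(20, 30, 40)
        ba = bland_altman(pairs(t, c))
        d = t - c
        assert ba.mean_diff == pytest.approx(d.mean(), abs=1e-12)
        assert ba.mean_diff == pytest.approx(t.mean() - c.mean(), abs=1e-9)
        assert ba.upper_loa == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))
        assert ba.lower_loa == pytest.approx(d.mean() - 1.96 * d.std(ddof=1))
        assert ba.mean_diff_ci[0] < ba.mean_diff < ba.mean_diff_ci[1]
        assert ba.lower_loa <= ba.mean_diff <= ba.upper_loa

    def test_loa_ci_uses_three_s_squared_over_n(self):
        rng = np.random.default_rng(2)
        c = rng.normal(0, 1, 20)
        t = c + rng.normal(0, 1, 20)
        d = t - c
        from scipy import stats
        tq = stats.t.ppf(0.975, 19)
        halfwidth = tq * np.sqrt(3 * d.var(ddof=1) / 20)
        ba = bland_altman(pairs(t, c))
        got = (ba.upper_loa_ci[1] - ba.upper_loa_ci[0]) / 2
        assert got == pytest.approx(halfwidth, abs=1e-12)


class TestGoalSensSpec:
    def test_perfect_agreement(self):
        s, p = goal_sens_spec(pairs([12000, 8000], [11000, 9000]))
        assert (s, p) == (1.0, 1.0)

    def test_contingency_arithmetic(self):
        # TP=5, FN=0, TN=3, FP=4
        crit = [11, 12, 13, 14, 15, 1, 2, 3, 4, 5, 6, 7]
        test = [11, 12, 13, 14, 15, 11, 12, 13, 14, 1, 2, 3]
        s, p = goal_sens_spec(pairs(test, crit), goal=10)
        assert s == pytest.approx(1.0)
        assert p == pytest.approx(3 / 7, abs=1e-4)

    def test_goal_boundary_is_inclusive(self):
        s, p = goal_sens_spec(pairs([10000], [10000]))
        assert s == 1.0 and p is None

    def test_no_criterion_positives_not_applicable(self):
        s, p = goal_sens_spec(pairs([12000, 9000], [8000, 7000]))
        assert s is None and p == pytest.approx(0.5)


class TestInterpretation:
    @pytest.mark.parametrize("r,label", [
        (0.75, "strong"), (0.85, "very strong"), (0.1, "very weak"),
        (-0.65, "strong"), (0.2, "weak"), (0.4, "moderate"),
        (0.6, "strong"), (0.8, "very strong"),
    ])
    def test_evans_bands(self, r, label):
        assert interpret_pearson(r) == label

    @pytest.mark.parametrize("ci,label", [
        ((0.45, 0.80), "poor to good"),
        ((0.92, 0.99), "excellent"),
        ((0.30, 0.45), "poor"),
        ((0.55, 0.95), "moderate to excellent"),
    ])
    def test_icc_ci_span_labels(self, ci, label):
        assert interpret_icc(ci) == label


class TestCompare:
    def test_full_battery_coherent(self):
        rng = np.random.default_rng(3)
        c = rng.normal(10000, 3000, 30)
        t = 1.1 * c + rng.normal(0, 800, 30)
        res = compare(pairs(t, c, "steps"), n_boot=300, seed=1)
        assert res.n == 30
        assert -1 <= res.pearson_r <= 1
        assert res.pearson_label == interpret_pearson(res.pearson_r)
        assert res.icc_label == interpret_icc(res.icc_ci)
        assert res.ba.lower_loa <= res.ba.mean_diff <= res.ba.upper_loa
        assert res.mape_pct >= 0
        assert 0 <= res.shapiro_p <= 1
        assert isinstance(spearman_rho(pairs(t, c)), float)
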