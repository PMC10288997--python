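import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from octamorph.group_stats import (
    SignificanceCategory,
    benjamini_hochberg,
    classify_p,
    logistic_adjusted,
    run_cohort_analysis,
    significance_map,
    t_test_samples,
    t_test_summary,
)
from octamorph.synthetic import cohort_spec_from_preset, simulate_cohort


class TestTTestSummary:
    def test_published_age_row_reproduces(self):
        """The demographic age comparison (eye-level n) gives p = 0.904."""
        for variant in ("welch", "pooled"):
            r = t_test_summary(47.36, 13.21, 50, 47.68, 12.48, 44, variant=variant)
            assert r.p == pytest.approx(0.904, abs=0.005)

    def test_identical_summaries(self):
        r = t_test_summary(5.0, 1.0, 10, 5.0, 1.0, 12)
        assert r.t == 0.0 and r.p == 1.0

    def test_zero_sd_degenerate_cases(self):
        equal = t_test_summary(3.0, 0.0, 5, 3.0, 0.0, 5)
        assert equal.p == 1.0 and not equal.degenerate
        unequal = t_test_summary(3.0, 0.0, 5, 4.0, 0.0, 5)
        assert unequal.p == 0.0 and unequal.degenerate

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            t_test_summary(1.0, 1.0, 1, 2.0, 1.0, 5)

    def test_against_t_distribution_oracle(self, rng):
        """p equals the survival integral of the t distribution."""
        for _ in range(200):
            m1, m2 = rng.normal(0, 5, 2)
            s1, s2 = rng.uniform(0.5, 4, 2)
            n1, n2 = rng.integers(5, 80, 2)
            r = t_test_summary(m1, s1, int(n1), m2, s2, int(n2))
            oracle = 2 * sps.t.sf(abs(r.t), r.df)
            assert r.p == pytest.approx(oracle, abs=1e-6)


class TestTTestSamples:
    def test_equal_samples_p_one(self, rng):
        x = rng.normal(0, 1, 20)
        r = t_test_samples(x, x.copy())
        assert r.p == pytest.approx(1.0)

    def test_consistent_with_summary_form(self, rng):
        for _ in range(20):
            x1 = rng.normal(0, 1, 25)
            x2 = rng.normal(0.4, 2, 31)
            rs = t_test_samples(x1, x2)
            rm = t_test_summary(
                x1.mean(), x1.std(ddof=1), x1.size, x2.mean(), x2.std(ddof=1), x2.size
            )
            assert rs.t == pytest.approx(rm.t, abs=1e-12)
            assert rs.p == pytest.approx(rm.p, abs=1e-12)

    def test_matches_scipy(self, rng):
        x1, x2 = rng.normal(0, 1, 30), rng.normal(0.5, 1.5, 40)
        r = t_test_samples(x1, x2)
        t, p = sps.ttest_ind(x1, x2, equal_var=False)
        assert r.t == pytest.approx(t) and r.p == pytest.approx(p)

    def test_permutation_agreement(self, rng):
        """Student-t p agrees with a permutation p on Gaussian data."""
        x1 = rng.normal(0.0, 1.0, 25)
        x2 = rng.normal(0.6, 1.0, 25)
        r = t_test_samples(x1, x2, variant="pooled")
        pooled = np.concatenate([x1, x2])
        n1 = x1.size
        count = 0
        n_perm = 4000
        obs = abs(x1.mean() - x2.mean())
        for _ in range(n_perm):
            rng.shuffle(pooled)
            if abs(pooled[:n1].mean() - pooled[n1:].mean()) >= obs:
                count += 1
        assert (count + 1) / (n_perm + 1) == pytest.approx(r.p, abs=0.02)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            t_test_samples([1.0], [2.0, 3.0])


class TestLogistic:
    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        n = 300
        tab = pd.DataFrame({"metric": rng.normal(0, 1, n), "age": rng.normal(50, 10, n)})
        lin = 0.7 * tab.metric - 0.03 * (tab.age - 50)
        tab["is_case"] = (rng.random(n) < 1 / (1 + np.exp(-lin))).astype(int)
        mine = logistic_adjusted(tab, "metric", covariates=("age",), standardized=False)
        ref = sm.Logit(tab.is_case, sm.add_constant(tab[["metric", "age"]])).fit(disp=0)
        assert mine.coef == pytest.approx(ref.params["metric"], abs=1e-6)
        assert mine.se == pytest.approx(ref.bse["metric"], abs=1e-6)
        assert mine.p == pytest.approx(ref.pvalues["metric"], abs=1e-6)

    def test_binary_metric_equals_cross_product_ratio(self, rng):
        x = rng.integers(0, 2, 600).astype(float)
        y = np.where(x == 1, rng.random(600) < 0.65, rng.random(600) < 0.35)
        tab = pd.DataFrame({"m": x, "is_case": y.astype(int)})
        r = logistic_adjusted(tab, "m", covariates=(), standardized=False)
        a = np.sum((x == 1) & y); b = np.sum((x == 1) & ~y)
        c = np.sum((x == 0) & y); d = np.sum((x == 0) & ~y)
        assert r.odds_ratio == pytest.approx(a * d / (b * c), rel=1e-6)

    def test_perfect_separation_flagged(self):
        tab = pd.DataFrame({"m": np.r_[np.zeros(20), np.ones(20)],
                            "is_case": np.r_[np.zeros(20), np.ones(20)].astype(int)})
        r = logistic_adjusted(tab, "m", covariates=(), standardized=False)
        assert r.separated
        assert r.odds_ratio in (0.0, float("inf"))

    def test_constant_covariate_dropped_with_warning(self, rng):
        n = 100
        tab = pd.DataFrame({
            "m": rng.normal(0, 1, n),
            "gender": np.zeros(n),
            "is_case": rng.integers(0, 2, n),
        })
        tab.loc[0, "is_case"] = 0
        tab.loc[1, "is_case"] = 1
        with pytest.warns(UserWarning, match="gender"):
            r = logistic_adjusted(tab, "m", covariates=("gender",))
        assert "gender" not in r.covariates

    def test_standardized_or_is_per_sd(self, rng):
        n = 4000
        raw = rng.normal(100.0, 20.0, n)
        lin = 0.05 * (raw - 100.0)
        y = (rng.random(n) < 1 / (1 + np.exp(-lin))).astype(int)
        tab = pd.DataFrame({"m": raw, "is_case": y})
        std = logistic_adjusted(tab, "m", covariates=())
        # generative OR per SD = exp(0.05 * 20)
        assert std.odds_ratio == pytest.approx(np.exp(1.0), rel=0.15)

    def test_wald_and_lr_p_agree_at_large_n(self, rng):
        import statsmodels.api as sm

        n = 500
        tab = pd.DataFrame({"m": rng.normal(0, 1, n)})
        lin = 0.3 * tab.m
        tab["is_case"] = (rng.random(n) < 1 / (1 + np.exp(-lin))).astype(int)
        mine = logistic_adjusted(tab, "m", covariates=(), standardized=False)
        full = sm.Logit(tab.is_case, sm.add_constant(tab[["m"]])).fit(disp=0)
        lr_p = full.llr_pvalue
        assert mine.p == pytest.approx(lr_p, abs=0.01)

    def test_missing_values_rejected(self):
        tab = pd.DataFrame({"m": [1.0, np.nan, 2.0, 0.5], "is_case": [0, 1, 0, 1]})
        with pytest.raises(ValueError, match="missing"):
            logistic_adjusted(tab, "m", covariates=())


class TestSignificanceMap:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.0005, SignificanceCategory.STRONG),
            (0.001, SignificanceCategory.STRONG),  # closed boundary
            (0.03, SignificanceCategory.SIGNIFICANT),
            (0.05, SignificanceCategory.SIGNIFICANT),
            (0.5, SignificanceCategory.NONE),
        ],
    )
    def test_thresholds(self, p, expected):
        assert classify_p(p) is expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_p(1.5)

    def test_map_applies_per_sector(self):
        out = significance_map({"SI": 0.0001, "TI": 0.02, "NE": 0.9})
        assert out["SI"] is SignificanceCategory.STRONG
        assert out["TI"] is SignificanceCategory.SIGNIFICANT
        assert out["NE"] is SignificanceCategory.NONE

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=200, deadline=None)
    def test_monotone_and_idempotent(self, p1, p2):
        order = [SignificanceCategory.STRONG, SignificanceCategory.SIGNIFICANT,
                 SignificanceCategory.NONE]
        lo, hi = min(p1, p2), max(p1, p2)
        assert order.index(classify_p(lo)) <= order.index(classify_p(hi))

    def test_bh_never_increases_significance(self, rng):
        ps = rng.random(40) * 0.2
        adj = benjamini_hochberg(ps)
        assert (adj >= ps - 1e-12).all()
        raw_sig = (ps <= 0.05).sum()
        assert (adj <= 0.05).sum() <= raw_sig


class TestCohortAnalysis:
    def test_report_dimensions(self):
        tab = simulate_cohort(cohort_spec_from_preset("nmosd_vs_hc", seed=0))
        rep = run_cohort_analysis(tab, contrast="nmosd-vs-hc")
        assert len(rep.t_tests) == 3 * 12
        assert len(rep.logistic) == 3 * 12
        assert rep.sector_categories is None

    def test_on_contrast(self):
        tab = simulate_cohort(cohort_spec_from_preset("on_vs_hc", seed=0))
        rep = run_cohort_analysis(tab, contrast="on-vs-hc")
        assert set(rep.t_tests.metric) == {
            c for c in tab.columns if c not in {"subject", "eye", "group", "age", "bmi", "bcva"}
        }

    def test_empty_group_rejected(self):
        tab = simulate_cohort(cohort_spec_from_preset("nmosd_vs_hc", seed=0))
        with pytest.raises(ValueError, match="empty group"):
            run_cohort_analysis(tab, contrast="on-vs-hc")

    def test_sector_columns_categorized(self, rng):
        n = 60
        rows = {"subject": [f"s{i}" for i in range(n)], "eye": ["OD"] * n,
                "group": ["HC"] * 30 + ["ON"] * 30,
                "age": rng.normal(50, 10, n), "bmi": rng.normal(22, 2, n),
                "bcva": rng.normal(1, 0.2, n),
                "SVC_SI_VAD": np.r_[rng.normal(15, 1, 30), rng.normal(10, 1, 30)],
                "SVC_NE_VAD": rng.normal(15, 1, n)}
        rep = run_cohort_analysis(pd.DataFrame(rows), contrast="on-vs-hc")
        cats = dict(zip(rep.sector_categories.sector, rep.sector_categories.category))
        assert cats["SI"] == "P<=0.001"
        assert cats["NE"] == "P>0.05"

    def test_strong_effects_significant_in_most_replicates(self):
        """Metrics reported as highly significant stay so in simulation."""
        strong = ["SVC_VAD", "SVC_VLD", "SVC_FD", "DVC_VAD", "DVC_VLD", "DVC_FD"]
        hits = {m: 0 for m in strong}
        n_rep = 50
        for seed in range(n_rep):
            tab = simulate_cohort(cohort_spec_from_preset("on_vs_hc", seed=seed))
            rep = run_cohort_analysis(tab, contrast="on-vs-hc")
            for m in strong:
                p = rep.t_tests.loc[rep.t_tests.metric == m, "p"].iloc[0]
                hits[m] += p < 0.01
        for m, h in hits.items():
            assert h / n_rep >= 0.90, m
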