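"""Survival separation, confusion at the 18-month horizon, risk ratios and
the nonparametric tests, each against an independent oracle."""

import numpy as np
import pandas as pd
import pytest

from ibdmark import (
    confusion_at_horizon,
    cox_hr,
    fisher_exact_2x2,
    kaplan_meier,
    logrank_test,
    mann_whitney,
    relative_risk,
)
from oracles import (
    cox_beta_numerical_oracle,
    efron_partial_loglik,
    fisher_two_tailed_enumeration,
    logrank_permutation_pvalue,
    mann_whitney_exact_enumeration,
)


class TestKaplanMeier:
    def test_no_events_curve_stays_at_one(self):
        km = kaplan_meier([1.0, 2.0, 3.0], [0, 0, 0])
        assert (km["survival"] == 1.0).all()

    def test_hand_product_limit(self):
        """times (1+, 2, 2, 3+): S(2) = 1 * (1 - 2/3) = 1/3, flat after."""
        km = kaplan_meier([1.0, 2.0, 2.0, 3.0], [0, 1, 1, 0]).set_index("time")
        assert km.loc[2.0, "survival"] == pytest.approx(1 / 3)
        assert km.loc[3.0, "survival"] == pytest.approx(1 / 3)

    def test_all_events_equals_ecdf_complement(self, rng):
        t = np.sort(rng.exponential(1.0, 25))
        km = kaplan_meier(t, np.ones(25, int)).set_index("time")
        for i, tt in enumerate(t):
            emp = 1.0 - (i + 1) / 25
            assert km.loc[tt, "survival"] == pytest.approx(emp, abs=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier([-1.0, 2.0], [1, 1])


class TestLogrank:
    def test_identical_groups_give_null_result(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0] * 2)
        e = np.array([1, 1, 0, 1, 1] * 2)
        g = np.array([0] * 5 + [1] * 5)
        chi2, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("seed", [2, 3])
    def test_matches_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.exponential(1.0, 20)
        g = np.array([0] * 10 + [1] * 10)
        t[g == 1] *= 0.55
        e = np.ones(20, int)
        _, p = logrank_test(t, e, g)
        p_perm = logrank_permutation_pvalue(t, e, g, n_perm=8000, seed=seed + 50)
        assert p == pytest.approx(p_perm, abs=0.02)

    def test_relabelling_invariance(self, rng):
        t = rng.exponential(1.0, 30)
        e = np.ones(30, int)
        g = np.array([0] * 15 + [1] * 15)
        chi2a, pa = logrank_test(t, e, g)
        chi2b, pb = logrank_test(t, e, 1 - g)
        assert chi2a == pytest.approx(chi2b, abs=1e-10)
        assert 0 <= pa <= 1 and pa == pytest.approx(pb, abs=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            logrank_test([1.0, 2.0], [1, 1], [0, 0])

    def test_power_at_planted_hazard_ratio(self):
        """HR=3 at n=500/arm is detected at p < 0.001 in >= 19/20 seeds."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            t0 = rng.exponential(1.0, 500)
            t1 = rng.exponential(1 / 3.0, 500)
            t = np.concatenate([t0, t1])
            e = (t <= 3.0).astype(int)
            t = np.minimum(t, 3.0)
            g = np.array([0] * 500 + [1] * 500)
            _, p = logrank_test(t, e, g)
            hits += p < 0.001
        assert hits >= 19


class TestCox:
    def _toy(self, seed, n=30, hr=2.0):
        rng = np.random.default_rng(seed)
        x = np.array([0, 1] * (n // 2), dtype=float)
        t = rng.exponential(1.0 / (1 + (hr - 1) * x))
        e = (t < 2.0).astype(int)
        t = np.minimum(t, 2.0)
        if e[x == 0].sum() == 0 or e[x == 1].sum() == 0:
            e[:2] = 1
        return t, e, x

    def test_partial_likelihood_matches_numerical_oracle(self):
        for seed in range(4):
            t, e, x = self._toy(seed)
            hr, _, _, _ = cox_hr(t, e, x)
            beta_oracle, ll_oracle = cox_beta_numerical_oracle(t, e, x)
            ll_ours = efron_partial_loglik(np.log(hr), t, e, x)
            assert ll_ours == pytest.approx(ll_oracle, abs=1e-8)
            assert np.log(hr) == pytest.approx(beta_oracle, abs=1e-5)

    def test_group_swap_gives_reciprocal_hr(self):
        t, e, x = self._toy(1)
        hr_a, *_ = cox_hr(t, e, x)
        hr_b, *_ = cox_hr(t, e, 1 - x)
        assert hr_a == pytest.approx(1 / hr_b, rel=1e-8)

    def test_null_simulation_is_unbiased(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(1.0, 4000)
        e = (t < 2.5).astype(int)
        t = np.minimum(t, 2.5)
        x = np.array([0.0, 1.0] * 2000)
        hr, lo, hi, _ = cox_hr(t, e, x)
        assert 0.8 <= hr <= 1.25
        assert lo <= hr <= hi

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            cox_hr([1.0, 2.0], [0, 0], [0.0, 1.0])


class TestConfusion:
    def _cohort(self, n=400, p_hi=0.7, p_lo=0.1, seed=5):
        rng = np.random.default_rng(seed)
        half = n // 2
        labels = ["IBDhi"] * half + ["IBDlo"] * half
        esc = np.concatenate([
            rng.binomial(1, p_hi, half) * 2, rng.binomial(1, p_lo, half) * 2,
        ])
        calls = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)],
                              "label": labels})
        clinical = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n)],
            "n_escalations_18m": esc,
            "followup_years": np.full(n, 3.0),
        })
        return calls, clinical

    def test_perfect_classifier(self):
        calls, clinical = self._cohort(p_hi=1.0, p_lo=0.0)
        c = confusion_at_horizon(calls, clinical)
        assert c.sensitivity == 1.0 and c.specificity == 1.0
        assert c.npv == 1.0 and c.ppv == 1.0

    def test_all_positive_calls_degenerate(self):
        calls, clinical = self._cohort()
        calls["label"] = "IBDhi"
        c = confusion_at_horizon(calls, clinical)
        assert c.sensitivity == 1.0
        assert c.specificity == 0.0
        assert np.isnan(c.npv) and (c.tn + c.fn) == 0

    def test_matches_planted_bernoulli_rates(self):
        """With planted escalation probabilities 0.7/0.1, sensitivity and NPV
        agree with their closed-form values within 0.05."""
        calls, clinical = self._cohort(n=400, p_hi=0.7, p_lo=0.1)
        c = confusion_at_horizon(calls, clinical)
        sens_true = 0.7 / (0.7 + 0.1)        # P(hi | escalated), equal arms
        npv_true = 0.9                        # IBDlo arm: P(no escalation) = 0.9
        assert c.sensitivity == pytest.approx(sens_true, abs=0.05)
        assert c.npv == pytest.approx(npv_true, abs=0.05)

    def test_censored_before_horizon_excluded(self):
        calls, clinical = self._cohort(n=40)
        clinical.loc[:9, "followup_years"] = 0.5
        clinical.loc[:9, "n_escalations_18m"] = 0
        c = confusion_at_horizon(calls, clinical)
        assert c.n_excluded == 10
        assert c.n_evaluable == 30


class TestKmPlot:
    def test_km_plot_truncates_at_display_horizon(self, rng):
        import matplotlib
        matplotlib.use("Agg")
        from ibdmark import compare_survival

        clin = pd.DataFrame({
            "time_years": np.minimum(rng.exponential(1.0, 40), 3.0),
            "event": np.ones(40, int),
        }, index=[f"s{i}" for i in range(40)])
        labels = pd.Series(["IBD1"] * 20 + ["IBD2"] * 20, index=clin.index)
        ax = compare_survival(clin, labels).plot_km(censor_at=1.5)
        assert len(ax.lines) == 2
        for line in ax.lines:
            assert line.get_xdata().max() <= 1.5 + 1e-12


class TestRelativeRisk:
    @pytest.mark.parametrize("a,n1,b,n2,expected", [
        (12, 33, 4, 33, 3.0),
        (8, 33, 15, 33, 0.53),
        (7, 24, 2, 28, 4.08),
    ])
    def test_worked_examples(self, a, n1, b, n2, expected):
        rr, lo, hi = relative_risk(a, n1, b, n2)
        assert round(rr, 2) == expected
        assert lo <= rr <= hi

    def test_reciprocal_product_is_one(self):
        rr1, *_ = relative_risk(5, 20, 7, 25)
        rr2, *_ = relative_risk(7, 25, 5, 20)
        assert rr1 * rr2 == pytest.approx(1.0, rel=1e-12)

    def test_zero_denominator_flagged_infinite(self):
        rr, lo, hi = relative_risk(3, 10, 0, 10)
        assert np.isinf(rr) and np.isnan(lo) and np.isnan(hi)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            relative_risk(11, 10, 1, 10)


class TestFisher:
    def test_colectomy_table_rounds_to_001(self):
        """7/56 vs 0/48 colectomies: two-tailed p rounds to 0.01."""
        p = fisher_exact_2x2(7, 49, 0, 48)
        assert round(p, 2) == 0.01

    def test_exchangeable_table_is_one(self):
        assert fisher_exact_2x2(5, 5, 5, 5) == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(25):
            a, b, c, d = rng.integers(0, 9, 4)
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            ours = fisher_exact_2x2(int(a), int(b), int(c), int(d))
            oracle = fisher_two_tailed_enumeration(int(a), int(b), int(c), int(d))
            assert ours == pytest.approx(oracle, abs=1e-12)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_exact_2x2(0, 0, 3, 4)


class TestMannWhitney:
    def test_identical_multisets(self):
        x = [1.0, 2.0, 2.0, 3.0]
        u, p = mann_whitney(x, list(x))
        assert u == len(x) ** 2 / 2
        assert p > 0.9

    def test_complete_separation(self):
        x = [1.0, 2.0, 3.0]
        y = [10.0, 11.0, 12.0, 13.0]
        u, _ = mann_whitney(x, y)
        assert u == 0.0

    def test_matches_exact_enumeration(self, rng):
        x = rng.normal(0, 1, 6)
        y = rng.normal(0.8, 1, 7)
        for alt in ("two-sided", "less", "greater"):
            _, p = mann_whitney(x, y, alternative=alt)
            p_oracle = mann_whitney_exact_enumeration(x, y, alternative=alt)
            assert p == pytest.approx(p_oracle, abs=1e-10)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mann_whitney([], [1.0])
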