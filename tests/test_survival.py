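import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test as lifelines_logrank
from scipy.optimize import minimize_scalar

from famvar import io, survival
from famvar.simulate import SyntheticConfig, generate_cohort
from famvar.survival import (
    cox_family_scan,
    cox_univariate,
    km_estimate,
    logrank,
    truncate_followup,
)


class TestTruncate:
    def test_rules(self):
        t, e = truncate_followup([70.0, 50.0], [1, 1], horizon=60)
        np.testing.assert_array_equal(t, [60.0, 50.0])
        np.testing.assert_array_equal(e, [0, 1])

    def test_empty(self):
        t, e = truncate_followup([], [], horizon=60)
        assert t.size == 0 and e.size == 0

    def test_bad_horizon(self):
        with pytest.raises(io.ValidationError):
            truncate_followup([1.0], [1], horizon=0)


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        curve = km_estimate([1, 2, 3, 4, 5], [1, 1, 1, 1, 1])
        steps = dict(zip(curve.times, curve.survival))
        for t, s in [(1, 0.8), (2, 0.6), (3, 0.4), (4, 0.2), (5, 0.0)]:
            assert steps[t] == pytest.approx(s)

    def test_all_censored_stays_at_one(self):
        curve = km_estimate([3, 5, 8], [0, 0, 0])
        assert np.all(curve.survival == 1.0)

    def test_hand_product_limit_with_censoring(self):
        # risk sets: t=1 -> 3 subjects (1 event), t=3 -> 1 subject (1 event)
        curve = km_estimate([1, 2, 3], [1, 0, 1])
        steps = dict(zip(curve.times, curve.survival))
        assert steps[1.0] == pytest.approx(2 / 3)
        assert steps[3.0] == pytest.approx(0.0)  # (2/3) * (1 - 1/1)

    def test_horizon_truncation_applied(self):
        curve = km_estimate([10, 70, 80], [1, 1, 1], horizon=60)
        assert curve.times.max() <= 60


def logrank_oracle(t, e, g):
    """Brute-force per-event-time O/E/V tabulation."""
    t, e, g = map(np.asarray, (t, e, g))
    in1 = g == np.unique(g)[0]
    o1 = e1 = v = 0.0
    for tk in sorted(set(t[e == 1])):
        risk = t >= tk
        n, n1 = risk.sum(), (risk & in1).sum()
        d = ((t == tk) & (e == 1)).sum()
        o1 += ((t == tk) & (e == 1) & in1).sum()
        e1 += d * n1 / n
        if n > 1:
            v += d * n1 * (n - n1) * (n - d) / (n**2 * (n - 1))
    return (o1 - e1) ** 2 / v


class TestLogRank:
    def test_identical_groups_null(self):
        t = [1, 2, 3, 1, 2, 3]
        e = [1, 1, 0, 1, 1, 0]
        g = [0, 0, 0, 1, 1, 1]
        res = logrank(t, e, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_label_swap_invariance_and_oe_balance(self, rng):
        t = rng.exponential(10, size=40)
        e = rng.integers(0, 2, size=40)
        e[0] = 1
        g = rng.integers(0, 2, size=40)
        g[:2] = [0, 1]
        res = logrank(t, e, g)
        res_swapped = logrank(t, e, 1 - g)
        assert res_swapped.statistic == pytest.approx(res.statistic, rel=1e-12)
        assert res.observed.sum() == pytest.approx(res.expected.sum(), abs=1e-9)

    def test_small_case_matches_brute_force_tabulation(self):
        t = [2, 4, 5, 1, 3, 6]
        e = [1, 1, 0, 1, 1, 1]
        g = [0, 0, 0, 1, 1, 1]
        res = logrank(t, e, g)
        assert res.statistic == pytest.approx(logrank_oracle(t, e, g), rel=1e-12)

    def test_agrees_with_lifelines(self, rng):
        t = rng.exponential(20, size=60)
        e = rng.integers(0, 2, size=60)
        g = rng.integers(0, 2, size=60)
        e[g == 0] |= 0
        res = logrank(t, e, g)
        ref = lifelines_logrank(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
        assert res.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
        assert res.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_no_events_degenerate(self):
        res = logrank([1, 2], [0, 0], [0, 1])
        assert res.degenerate and res.p_value == 1.0


def breslow_neg_loglik(beta, x, t, e):
    """Tie-free partial log-likelihood (Breslow = Efron without ties)."""
    ll = 0.0
    for i in np.where(e == 1)[0]:
        risk = t >= t[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return -ll


class TestCox:
    @pytest.fixture
    def tiefree8(self, rng):
        x = rng.normal(size=8)
        t = rng.exponential(10 * np.exp(-0.5 * x))
        e = np.array([1, 1, 1, 0, 1, 1, 0, 1])
        return x, t, e

    def test_constant_covariate_rejected(self):
        with pytest.raises(io.ValidationError, match="constant"):
            cox_univariate([1, 1, 1], [1, 2, 3], [1, 1, 0])

    def test_sign_flip_inverts_hazard_ratio(self, tiefree8):
        x, t, e = tiefree8
        hr = cox_univariate(x, t, e).hr
        hr_neg = cox_univariate(-x, t, e).hr
        assert hr_neg == pytest.approx(1 / hr, rel=1e-6)

    def test_matches_partial_likelihood_oracle(self, tiefree8):
        x, t, e = tiefree8
        res = cox_univariate(x, t, e)
        opt = minimize_scalar(
            breslow_neg_loglik, bounds=(-5, 5), args=(x, t, e), method="bounded",
            options={"xatol": 1e-10},
        )
        assert res.beta == pytest.approx(opt.x, abs=1e-6)
        assert res.ci_low <= res.hr <= res.ci_high

    def test_score_test_at_zero_equals_logrank(self, rng):
        # classical identity for a tie-free binary covariate
        g = np.repeat([0, 1], 15)
        t = rng.exponential(np.where(g == 1, 6.0, 12.0)) + rng.uniform(0, 1e-6, 30)
        e = np.ones(30, dtype=int)
        e[rng.integers(0, 30, 5)] = 0
        assert np.unique(t).size == 30  # tie-free
        u = i_info = 0.0
        for j in np.where(e == 1)[0]:
            risk = t >= t[j]
            xbar = g[risk].mean()
            u += g[j] - xbar
            i_info += g[risk].var()
        score_stat = u**2 / i_info
        lr = logrank(t, e, g)
        assert score_stat == pytest.approx(lr.statistic, abs=1e-6)

    def test_parameter_recovery_quick(self, rng):
        # true log-HR 0.69 per unit at n = 400: estimate lands nearby
        x = rng.normal(size=400)
        t = rng.exponential(1.0 / (0.05 * np.exp(np.log(2.0) * x)))
        e = np.ones(400, dtype=int)
        res = cox_univariate(x, t, e)
        assert res.beta == pytest.approx(np.log(2.0), abs=0.15)


class TestFamilyScan:
    def test_table_shape_on_synthetic_cohort(self):
        cohort = generate_cohort(SyntheticConfig(seed=3, n_per_class=60))
        fam = io.load_builtin_family("ALDH")
        scan = cox_family_scan(cohort.matrix, fam, cohort.clinical)
        assert set(scan["class_label"]) == set(cohort.config.class_labels)
        assert set(scan.columns) >= {"gene", "hr", "ci_low", "ci_high", "p", "n", "events"}
        assert ((scan["ci_low"] <= scan["hr"]) & (scan["hr"] <= scan["ci_high"])).all()
        assert (scan.groupby("class_label")["gene"].count() <= 19).all()

    def test_low_event_cohort_skipped(self, small_matrix):
        clin = io.ClinicalTable(
            pd.DataFrame(
                {
                    "class_label": ["A"] * 4,
                    "time": [10.0, 20.0, 30.0, 40.0],
                    "event": [0, 0, 0, 1],
                },
                index=pd.Index([f"S{i}" for i in range(4)], name="sample_id"),
            )
        )
        fam = io.GeneFamily("D", ("GENEA", "GENEB"))
        scan = cox_family_scan(small_matrix, fam, clin)
        assert scan.empty

    def test_null_covariate_ci_covers_one(self, rng):
        # genes unrelated to survival: CI for HR should usually cover 1
        cover = 0
        n_rep = 60
        for _ in range(n_rep):
            x = rng.normal(size=120)
            t = rng.exponential(20, size=120)
            e = (rng.uniform(size=120) < 0.6).astype(int)
            res = cox_univariate(x, t, e)
            cover += res.ci_low <= 1.0 <= res.ci_high
        assert cover / n_rep >= 0.90
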