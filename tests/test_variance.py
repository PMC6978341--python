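import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from famvar import io, variance
from famvar.variance import (
    FamilyVarianceResult,
    UndefinedProfileError,
    avs,
    avs_max,
    percent_of_family,
    score_cohort,
    stratify,
)


def profile(values):
    return percent_of_family(np.asarray(values, dtype=float), sample_id="t")


class TestPercentOfFamily:
    def test_equal_values_give_uniform_percents(self):
        p = profile([10.0] * 19)
        np.testing.assert_allclose(p.percents, 100.0 / 19, rtol=1e-12)
        assert p.percents.sum() == pytest.approx(100.0, abs=1e-9)

    def test_simple_arithmetic(self):
        p = profile([300, 100] + [0] * 17)
        np.testing.assert_allclose(p.percents[:2], [75.0, 25.0])
        assert p.percents[2:].sum() == 0

    def test_all_zero_is_undefined(self):
        with pytest.raises(UndefinedProfileError):
            profile([0.0] * 19)

    def test_negative_rejected(self):
        with pytest.raises(io.ValidationError):
            profile([1.0, -1.0, 2.0])


class TestScoreValue:
    def test_uniform_profile_scores_zero(self):
        assert avs(profile([5.0] * 19)).avs == pytest.approx(0.0, abs=1e-12)

    def test_single_member_attains_maximum(self):
        # closed form 100^2 (n-1)/n^2 for one nonzero member
        res = avs(profile([100.0] + [0.0] * 18))
        assert res.avs == pytest.approx(10000 * 18 / 361, rel=1e-12)
        assert res.avs == pytest.approx(avs_max(19), rel=1e-12)

    def test_two_member_value_matches_hand_sum(self):
        # mean = 100/19; brute-force sum of squared deviations / 19
        x = np.array([60.0, 40.0] + [0.0] * 17)
        expected = float(np.sum((x - x.mean()) ** 2) / 19)
        assert expected == pytest.approx(245.9834, abs=5e-5)
        assert avs(profile(x)).avs == pytest.approx(expected, rel=1e-12)

    @given(
        st.lists(st.floats(0.01, 1e6), min_size=2, max_size=30),
        st.floats(1e-3, 1e3),
    )
    def test_scale_invariance(self, values, c):
        v = np.asarray(values)
        a1 = avs(percent_of_family(v)).avs
        a2 = avs(percent_of_family(c * v)).avs
        assert a2 == pytest.approx(a1, abs=1e-9)

    @given(st.lists(st.floats(0.0, 1e4), min_size=2, max_size=30).filter(lambda v: sum(v) > 0))
    def test_permutation_invariance_and_bounds(self, values):
        v = np.asarray(values)
        rs = np.random.default_rng(0)
        a1 = avs(percent_of_family(v)).avs
        a2 = avs(percent_of_family(rs.permutation(v))).avs
        assert a2 == pytest.approx(a1, rel=1e-12, abs=1e-12)
        assert -1e-12 <= a1 <= avs_max(v.size) + 1e-9

    def test_oracle_equivalence_on_random_profiles(self, rng):
        # naive two-pass population variance as the independent oracle
        for _ in range(1000):
            n = rng.integers(2, 40)
            v = rng.gamma(0.5, 10.0, size=n) + 1e-9
            x = 100 * v / v.sum()
            oracle = float(np.var(x))
            assert avs(percent_of_family(v)).avs == pytest.approx(oracle, rel=1e-12)


class TestScoreCohort:
    def test_one_result_per_sample(self, rng):
        fam = io.load_builtin_family("ALDH")
        df = pd.DataFrame(
            rng.uniform(0, 100, size=(5, 19)),
            index=[f"S{i}" for i in range(5)],
            columns=list(fam.members),
        )
        out = score_cohort(io.ExpressionMatrix(df), fam)
        assert len(out.results) == 5
        assert out.undefined_samples == []
        assert all(r.n_members == 19 for r in out.results)

    def test_missing_member_policies(self, rng):
        fam = io.load_builtin_family("ALDH")
        cols = [g for g in fam.members if g != "ALDH16A1"]
        df = pd.DataFrame(
            rng.uniform(1, 100, size=(3, 18)),
            index=["S0", "S1", "S2"],
            columns=cols,
        )
        m = io.ExpressionMatrix(df)
        with pytest.raises(io.ValidationError, match="ALDH16A1"):
            score_cohort(m, fam, missing_policy="error")
        out = score_cohort(m, fam, missing_policy="zero")
        assert all(r.n_missing_in_matrix == 1 and r.n_members == 19 for r in out.results)

    def test_zero_total_sample_listed_separately(self):
        fam = io.GeneFamily("D", ("G1", "G2"))
        df = pd.DataFrame(
            [[1.0, 2.0], [0.0, 0.0]], index=["ok", "empty"], columns=["G1", "G2"]
        )
        out = score_cohort(io.ExpressionMatrix(df), fam)
        assert [r.sample_id for r in out.results] == ["ok"]
        assert out.undefined_samples == ["empty"]


def results(values):
    return [FamilyVarianceResult(f"S{i}", float(v), 19) for i, v in enumerate(values)]


class TestStratify:
    def test_median_rule_ties_go_low(self):
        groups = [g.group for g in stratify(results([1, 2, 3, 4]), rule="median")]
        assert groups == ["low", "low", "high", "high"]
        # a sample exactly at the median is "low"
        groups = [g.group for g in stratify(results([1, 2, 3]), rule="median")]
        assert groups == ["low", "low", "high"]

    def test_quartile25_rule(self):
        out = stratify(results(range(1, 9)), rule="quartile25")
        assert sum(g.group == "low" for g in out) == 2
        assert out[0].threshold_value == pytest.approx(np.percentile(range(1, 9), 25))

    def test_identical_scores_degenerate(self, caplog):
        with caplog.at_level("WARNING"):
            out = stratify(results([5, 5, 5]), rule="median")
        assert all(g.group == "low" for g in out)
        assert "degenerate" in caplog.text

    def test_needs_two_samples(self):
        with pytest.raises(io.ValidationError):
            stratify(results([1.0]), rule="median")
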