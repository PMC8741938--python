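"""Statistical battery: group tests, Youden cutoff, logistic and ordinal
odds ratios."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from oracles import brute_force_youden

from ringmorph import cohort_stats as cs


class TestTwoGroupTest:
    def test_identical_groups_t_zero_p_one(self):
        t, p = cs.two_group_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    @pytest.mark.parametrize("method,n", [("t", 3), ("mannwhitney", 8)])
    def test_separated_groups_significant(self, method, n):
        # the exact Mann-Whitney two-sided p is bounded below by 2/C(2n, n),
        # so the rank test needs n=8 per group to reach p < 0.01
        a = list(range(1, n + 1))
        b = [x + 100 for x in a]
        _, p = cs.two_group_test(a, b, method=method)
        assert p < 0.01

    def test_mannwhitney_u_half_n_squared_on_identical_multisets(self):
        a = [3.0, 1.0, 2.0, 5.0]
        u, _ = cs.two_group_test(a, list(reversed(a)), method="mannwhitney")
        assert u == pytest.approx(len(a) ** 2 / 2)

    def test_welch_default_matches_scipy(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 2, 12)
        t, p = cs.two_group_test(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert (t, p) == (pytest.approx(ref.statistic), pytest.approx(ref.pvalue))

    def test_too_small_group_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            cs.two_group_test([1.0], [1.0, 2.0])


class TestMultiGroupTest:
    def test_three_identical_groups_h_zero(self):
        r = cs.multi_group_test([[1, 2, 3]] * 3)
        assert r.statistic == pytest.approx(0.0) and r.p == pytest.approx(1.0)

    def test_disjoint_ranges_significant(self):
        r = cs.multi_group_test([[1, 2, 3, 4], [11, 12, 13, 14], [21, 22, 23, 24]])
        assert r.p < 0.01

    def test_tukey_on_equal_mean_groups_near_one(self):
        r = cs.multi_group_test([[1, 2, 3, 4]] * 3, posthoc=True)
        assert (r.posthoc["p-adj"].astype(float) > 0.99).all()

    def test_two_groups_redirects(self):
        with pytest.raises(ValueError, match="two_group_test"):
            cs.multi_group_test([[1, 2], [3, 4]])


class TestYoudenCutoff:
    def test_perfect_separation_j_one(self):
        r = cs.youden_cutoff([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert r.j == pytest.approx(1.0)
        assert 0.2 < r.cutoff < 0.8

    def test_uninformative_constant_scores_j_zero(self):
        r = cs.youden_cutoff([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1])
        assert r.j == pytest.approx(0.0)

    def test_worked_example_matches_exhaustive_search(self):
        scores, labels = [0.1, 0.4, 0.35, 0.8], [0, 1, 0, 1]
        r = cs.youden_cutoff(scores, labels)
        cut_ref, j_ref = brute_force_youden(scores, labels)
        assert r.j == pytest.approx(j_ref)
        assert r.cutoff == pytest.approx(cut_ref)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="both outcome classes"):
            cs.youden_cutoff([0.1, 0.9], [1, 1])

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.data())
    def test_matches_brute_force_on_random_instances(self, data):
        n = data.draw(st.integers(4, 30))
        scores = data.draw(
            st.lists(st.floats(0, 1, width=32, allow_nan=False), min_size=n, max_size=n)
        )
        labels = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        if len(set(labels)) < 2:
            labels[0], labels[-1] = 0, 1
        r = cs.youden_cutoff(scores, labels)
        cut_ref, j_ref = brute_force_youden(scores, labels)
        assert r.j == pytest.approx(j_ref, abs=1e-12)
        assert r.cutoff == pytest.approx(cut_ref, abs=1e-12)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(shift=st.floats(-100, 100, allow_nan=False))
    def test_shift_equivariance(self, shift):
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.55])
        labels = np.array([0, 1, 0, 1, 1])
        base = cs.youden_cutoff(scores, labels)
        moved = cs.youden_cutoff(scores + shift, labels)
        assert moved.j == pytest.approx(base.j)
        assert moved.cutoff == pytest.approx(base.cutoff + shift, abs=1e-9)


class TestBinaryLogit:
    def test_two_by_two_equals_cross_product_odds_ratio(self):
        a, b, c, d = 17, 8, 6, 21
        x = np.r_[np.ones(a + b), np.zeros(c + d)]
        y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        est = cs.binary_logit_hr(y, x)[0]
        assert est.hr == pytest.approx((a * d) / (b * c), abs=1e-6)

    def test_predictor_equals_outcome_flags_separation(self):
        y = np.array([0.0, 0, 0, 1, 1, 1])
        with pytest.warns(UserWarning, match="separation"):
            est = cs.binary_logit_hr(y, y + 0.0)[0]
        assert est.hr == math.inf and est.note == "perfect separation"
        assert math.isnan(est.p)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cs.binary_logit_hr([0, 1, 0, 1], [2.0, 2.0, 2.0, 2.0])

    def test_multivariable_fit_returns_one_estimate_per_predictor(self, rng):
        x = rng.normal(size=(120, 2))
        p = 1 / (1 + np.exp(-(0.8 * x[:, 0] - 0.5 * x[:, 1])))
        y = (rng.random(120) < p).astype(float)
        ests = cs.binary_logit_hr(y, x, names=["u", "v"])
        assert [e.variable for e in ests] == ["u", "v"]
        assert all(e.ci_low <= e.hr <= e.ci_high for e in ests)


class TestOrdinalLogit:
    def test_two_level_outcome_reduces_to_binary_logit(self, rng):
        x = rng.normal(size=(200, 2))
        p = 1 / (1 + np.exp(-(0.6 * x[:, 0] - 0.4 * x[:, 1] + 0.3)))
        y = (rng.random(200) < p).astype(int)
        binary = cs.binary_logit_hr(y, x, names=["u", "v"])
        ordinal, _ = cs.ordinal_logit(y + 1, x, names=["u", "v"])
        for b, o in zip(binary, ordinal):
            assert abs(b.coef - o.coef) < 1e-6

    def test_known_beta_recovered_within_two_se(self, rng):
        hits = 0
        n_rep = 40
        for _ in range(n_rep):
            x = rng.normal(size=300)
            u = 0.8 * x + rng.logistic(size=300)
            y = np.digitize(u, [-1.0, 0.5, 1.5]) + 1
            est, _ = cs.ordinal_logit(y, x, names=["x"])
            if abs(est[0].coef - 0.8) <= 2 * est[0].se:
                hits += 1
        lo, _ = stats.binom.interval(0.95, n_rep, 0.95)
        assert hits >= lo

    def test_type_one_error_near_nominal_under_null(self, rng):
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            x = rng.normal(size=400)
            y = np.digitize(rng.logistic(size=400), [-1.0, 0.3, 1.5]) + 1
            est, _ = cs.ordinal_logit(y, x, names=["x"])
            if est[0].p < 0.05:
                rejections += 1
        lo, hi = stats.binom.interval(0.95, n_rep, 0.05)
        assert lo <= rejections <= hi

    def test_single_level_outcome_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            cs.ordinal_logit(np.ones(10), np.arange(10.0))

    def test_thresholds_increasing(self, rng):
        x = rng.normal(size=400)
        y = np.digitize(0.5 * x + rng.logistic(size=400), [-1.0, 0.3, 1.5]) + 1
        _, thr = cs.ordinal_logit(y, x)
        assert (np.diff(thr) > 0).all()


class TestForestTable:
    def _cohort(self, rng, effect=2.0, n=40):
        import pandas as pd

        y = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        return pd.DataFrame(
            {
                "ln_status": y,
                "ep_sd": rng.normal(0.06, 0.012, n) + 0.024 * y * effect / 2.0,
                "sc_mean": rng.normal(2000, 50, n),
                "flat": np.ones(n),
            }
        )

    def test_shifted_variable_has_hr_above_one_and_significant(self, rng):
        table = cs.forest_table(self._cohort(rng), "ln_status", ["ep_sd", "sc_mean"])
        row = table.set_index("variable").loc["ep_sd"]
        assert row["hr"] > 1.0
        assert row["p"] < 0.05

    def test_zero_variance_variable_excluded(self, rng):
        table = cs.forest_table(self._cohort(rng), "ln_status", ["ep_sd", "flat"])
        assert "flat" not in set(table["variable"])

    def test_continuous_mode_returns_continuous_hrs(self, rng):
        table = cs.forest_table(
            self._cohort(rng), "ln_status", ["ep_sd"], dichotomize=False
        )
        assert table.loc[0, "cutoff"] is None or np.isnan(table.loc[0, "cutoff"])
        assert table.loc[0, "hr"] > 1.0

    def test_separated_dichotomized_variable_gets_continuity_correction(self, rng):
        import pandas as pd

        # groups fully separated on the marker: the 2x2 at the Youden
        # cutoff has empty cells; the corrected OR must be finite,
        # in the right direction, and flagged on the row
        cohort = pd.DataFrame(
            {
                "ln_status": np.r_[np.zeros(10), np.ones(10)],
                "marker": np.r_[rng.normal(0, 0.5, 10), rng.normal(10, 0.5, 10)],
            }
        )
        table = cs.forest_table(cohort, "ln_status", ["marker"])
        row = table.iloc[0]
        assert np.isfinite(row["hr"]) and row["hr"] > 1
        assert row["p"] < 0.05
        assert "continuity" in row["note"]

    def test_rows_follow_requested_order(self, rng):
        table = cs.forest_table(self._cohort(rng), "ln_status", ["sc_mean", "ep_sd"])
        assert list(table["variable"]) == ["sc_mean", "ep_sd"]
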