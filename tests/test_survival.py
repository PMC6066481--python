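"""Nonparametric estimators and two-sample tests against independent oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from markerpipe.errors import (
    DegenerateGroupsError,
    InvalidInputError,
    NoEventsError,
)
from markerpipe.survival import (
    cuminc_estimate,
    gray_test,
    km_estimate,
    logrank_test,
    survival_at,
)


def _two_group_data(rng, n, hr=1.0, censor_scale=None, two_causes=False):
    g = rng.binomial(1, 0.5, n)
    t = rng.exponential(1.0 / (0.5 * hr**g))
    c = rng.exponential(censor_scale, n) if censor_scale else np.full(n, np.inf)
    obs = np.minimum(t, c)
    ev = (t <= c).astype(int)
    if two_causes:
        cause = np.where(ev == 1, rng.integers(1, 3, n), 0)
        return obs, cause, g
    return obs, ev, g


class TestKaplanMeier:
    def test_hand_product_limit(self):
        # events at t=1 and t=3, censorings at t=2 and t=4
        est = km_estimate([1, 2, 3, 4], [1, 0, 1, 0])
        np.testing.assert_allclose(est.survival, [0.75, 0.375])
        np.testing.assert_array_equal(est.at_risk, [4, 2])
        # Greenwood: S^2 * sum d/(n(n-d))
        np.testing.assert_allclose(
            est.variance,
            [0.75**2 * (1 / 12), 0.375**2 * (1 / 12 + 1 / 2)],
        )

    def test_no_events_survival_is_one(self):
        est = km_estimate([1.0, 2.0], [0, 0])
        assert est.event_times.size == 0
        assert survival_at(est, 5.0) == 1.0

    def test_negative_time_rejected(self):
        with pytest.raises(InvalidInputError):
            km_estimate([-1.0, 2.0], [1, 0])

    @given(st.integers(0, 10_000))
    def test_no_censoring_equals_one_minus_ecdf(self, seed):
        r = np.random.default_rng(seed)
        t = np.round(r.exponential(1, 30), 2)  # rounding induces ties
        est = km_estimate(t, np.ones(30, dtype=int))
        for tt, s in zip(est.event_times, est.survival):
            assert s == pytest.approx((t > tt).mean(), abs=1e-12)

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        t = rng.exponential(1, 300)
        c = rng.exponential(1.5, 300)
        obs, ev = np.minimum(t, c), (t <= c).astype(int)
        est = km_estimate(obs, ev)
        kmf = KaplanMeierFitter().fit(obs, ev)
        ref = kmf.survival_function_.loc[est.event_times].to_numpy().ravel()
        np.testing.assert_allclose(est.survival, ref, atol=1e-12)

    def test_survival_at_step_convention(self):
        est = km_estimate([1, 2, 3, 4], [1, 0, 1, 0])
        assert survival_at(est, 0) == 1.0
        assert survival_at(est, 2.5) == 0.75  # between event times
        assert survival_at(est, 3.0) == 0.375  # right-continuous at the jump
        assert survival_at(est, 100.0) == 0.375  # flat beyond follow-up
        value, extrapolated = survival_at(est, 100.0, return_flag=True)
        assert value == 0.375 and extrapolated
        assert survival_at(est, 3.5, return_flag=True) == (0.375, False)

    def test_exponential_cohort_matches_closed_form(self):
        r = np.random.default_rng(7)
        lam = 0.3
        t = r.exponential(1 / lam, 5000)
        est = km_estimate(t, np.ones(5000, dtype=int))
        for tt in (0.5, 1.0, 2.0):
            assert survival_at(est, tt) == pytest.approx(np.exp(-lam * tt), abs=0.02)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 1, 0, 1, 1, 1, 0, 1]
        g = [0, 0, 0, 0, 1, 1, 1, 1]
        res = logrank_test(t, e, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_single_group_rejected(self):
        with pytest.raises(DegenerateGroupsError):
            logrank_test([1, 2], [1, 1], [1, 1])

    def test_extreme_separation(self, rng):
        t = np.concatenate([rng.uniform(0, 1, 100), rng.uniform(10, 11, 100)])
        e = np.ones(200, dtype=int)
        g = np.repeat([0, 1], 100)
        assert logrank_test(t, e, g).p_value < 0.001

    def test_permutation_reference_small_n(self):
        # chi-square p within Monte-Carlo error of a 20,000-permutation
        # reference at n=8
        r = np.random.default_rng(11)
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        e = np.array([1, 1, 0, 1, 1, 0, 1, 1])
        g = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        obs = logrank_test(t, e, g)
        count = 0
        n_perm = 20_000
        for _ in range(n_perm):
            gp = r.permutation(g)
            count += logrank_test(t, e, gp).statistic >= obs.statistic - 1e-12
        p_perm = count / n_perm
        # permutation p is discrete and conservative at tiny n; require the
        # chi-square p to sit within 3 MC standard errors + discreteness slack
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(obs.p_value - p_perm) < 0.12 + 3 * se

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll

        obs, ev, g = _two_group_data(rng, 150, hr=1.5, censor_scale=2.0)
        mine = logrank_test(obs, ev, g)
        ref = ll(obs[g == 1], obs[g == 0], ev[g == 1], ev[g == 0])
        assert mine.statistic == pytest.approx(ref.test_statistic, rel=1e-10)
        assert mine.p_value == pytest.approx(ref.p_value, rel=1e-10)

    def test_invariant_under_time_rescaling(self, rng):
        obs, ev, g = _two_group_data(rng, 80, hr=2.0, censor_scale=2.0)
        a = logrank_test(obs, ev, g)
        b = logrank_test(np.sqrt(obs), ev, g)  # strictly increasing map
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)


class TestCumulativeIncidence:
    def test_single_cause_equals_one_minus_km(self, rng):
        obs, ev, _ = _two_group_data(rng, 200, censor_scale=2.0)
        km = km_estimate(obs, ev)
        (cif,) = cuminc_estimate(obs, ev)
        np.testing.assert_allclose(cif.cif, 1 - km.survival, atol=1e-12)
        # with one cause the variance reduces to Greenwood's
        np.testing.assert_allclose(cif.variance, km.variance, atol=1e-10)

    def test_cif_sum_plus_event_free_is_one(self, rng):
        obs, cause, _ = _two_group_data(rng, 300, censor_scale=1.5, two_causes=True)
        cifs = cuminc_estimate(obs, cause)
        km_all = km_estimate(obs, (cause > 0).astype(int))
        total = sum(c.cif for c in cifs)
        np.testing.assert_allclose(total + km_all.survival, 1.0, atol=1e-10)

    def test_matches_scikit_survival(self, rng):
        from sksurv.nonparametric import cumulative_incidence_competing_risks

        obs, cause, _ = _two_group_data(rng, 250, censor_scale=1.5, two_causes=True)
        cifs = cuminc_estimate(obs, cause)
        tt, ci = cumulative_incidence_competing_risks(cause, obs)
        for est in cifs:
            idx = np.searchsorted(tt, est.event_times)
            np.testing.assert_allclose(est.cif, ci[est.cause][idx], atol=1e-12)

    def test_competing_exponentials_analytic_limit(self):
        # lambda_r = lambda_d: CIF_relapse(inf) -> 1/2
        r = np.random.default_rng(5)
        n = 20_000
        t1 = r.exponential(1.0, n)
        t2 = r.exponential(1.0, n)
        obs = np.minimum(t1, t2)
        cause = np.where(t1 <= t2, 1, 2)
        cif = cuminc_estimate(obs, cause)[0]
        assert cif.cif[-1] == pytest.approx(0.5, abs=0.02)

    def test_all_censored_cifs_zero(self):
        cifs = cuminc_estimate([0.1, 0.2, 0.3], [0, 0, 0])
        assert cifs == []

    def test_unknown_cause_code_rejected(self):
        with pytest.raises(InvalidInputError):
            cuminc_estimate([1.0, 2.0], [1, -2])


class TestGray:
    def test_identical_groups(self):
        t = np.tile([1.0, 2, 3, 4, 5, 6], 2)
        cause = np.tile([1, 2, 0, 1, 2, 0], 2)
        g = np.repeat([0, 1], 6)
        res = gray_test(t, cause, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)

    def test_no_events_of_cause_rejected(self):
        with pytest.raises(NoEventsError):
            gray_test([1, 2, 3, 4], [2, 2, 0, 2], [0, 1, 0, 1], cause_of_interest=1)

    def test_permutation_reference_two_causes(self):
        r = np.random.default_rng(3)
        obs, cause, g = _two_group_data(r, 30, hr=2.0, censor_scale=2.0, two_causes=True)
        chi2_p = gray_test(obs, cause, g).p_value
        perm = gray_test(obs, cause, g, n_permutations=20_000, seed=1)
        se = np.sqrt(perm.p_value * (1 - perm.p_value) / 20_000)
        assert abs(chi2_p - perm.p_value) < 0.08 + 3 * se

    def test_no_competing_events_close_to_logrank(self):
        # single-cause data: Gray's and the log-rank permutation reference
        # answer the same question
        r = np.random.default_rng(9)
        obs, ev, g = _two_group_data(r, 40, hr=2.5, censor_scale=2.0)
        gray_p = gray_test(obs, ev, g).p_value
        count = 0
        base = logrank_test(obs, ev, g)
        for _ in range(20_000):
            gp = r.permutation(g)
            count += logrank_test(obs, ev, gp).statistic >= base.statistic - 1e-12
        p_perm = count / 20_000
        se = np.sqrt(max(p_perm * (1 - p_perm), 1e-9) / 20_000)
        assert abs(gray_p - p_perm) < 0.08 + 3 * se

    def test_agrees_with_cmprsk_fixture(self):
        # frozen cross-check against R cmprsk::cuminc on the same data
        # (seed 7 fixture): cmprsk reports chi2 = 3.8298 (cause 1) and
        # 5.1247 (cause 2)
        r = np.random.default_rng(7)
        n = 120
        t = r.exponential(1, n)
        c = r.exponential(1.2, n)
        obs, ev = np.minimum(t, c), (t <= c).astype(int)
        cause = np.where(ev == 1, r.integers(1, 3, n), 0)
        g = r.binomial(1, 0.5, n)
        chi1 = gray_test(obs, cause, g, cause_of_interest=1).statistic
        chi2 = gray_test(obs, cause, g, cause_of_interest=2).statistic
        assert chi1 == pytest.approx(3.8298, abs=0.35)
        assert chi2 == pytest.approx(5.1247, abs=0.55)
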