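"""Logistic and Cox fits, the PH check and the Lunn–McNeil extension."""

import numpy as np
import pandas as pd
import pytest

import markerpipe as mp
from markerpipe._cox import cox_newton, episode_split
from markerpipe.errors import (
    InvalidInputError,
    NoEventsError,
    SeparationError,
)
from markerpipe.regression import (
    ModelSpec,
    cox_fit,
    logistic_fit,
    lunn_mcneil_fit,
    ph_test,
)


def cohort_with_status(n, seed, prevalence=0.25, **cfg_kwargs):
    cfg = mp.CohortConfig(n_patients=n, n_genes=1, seed=seed, **cfg_kwargs)
    truth = np.random.default_rng(seed + 10_000).random(n) < prevalence
    cohort = mp.generate_clinical(cfg, truth)
    cohort.data["marker_status"] = np.where(truth, "H+", "H-")
    return cohort


class TestModelSpec:
    def test_hsct_forbidden_in_cr_model(self):
        with pytest.raises(InvalidInputError):
            ModelSpec("cr", ("marker", "hsct_td"))

    def test_interaction_requires_main_effects(self):
        with pytest.raises(InvalidInputError):
            ModelSpec("os", ("marker", "npm1_flt3_interaction"))

    def test_standard_spec_includes_hsct_for_survival_only(self):
        assert "hsct_td" in ModelSpec.standard("os").terms
        assert "hsct_td" not in ModelSpec.standard("cr").terms


class TestCoxEngine:
    def test_matches_lifelines_with_ties(self):
        from lifelines import CoxPHFitter

        r = np.random.default_rng(3)
        n = 600
        X = np.c_[r.binomial(1, 0.3, n), r.normal(size=n)]
        t = np.ceil(r.exponential(1 / (0.01 * np.exp(X @ [0.7, -0.3]))))
        c = r.exponential(250, n)
        obs, ev = np.minimum(t, c), (t <= c).astype(int)
        mine = cox_newton(X, np.zeros(n), obs, ev)
        ref = CoxPHFitter().fit(
            pd.DataFrame(np.c_[X, obs, ev], columns=["x1", "x2", "T", "E"]), "T", "E"
        )
        np.testing.assert_allclose(mine.beta, ref.params_.to_numpy(), atol=2e-5)
        np.testing.assert_allclose(
            np.sqrt(np.diag(mine.cov)), ref.standard_errors_.to_numpy(), atol=2e-5
        )
        assert mine.loglik == pytest.approx(ref.log_likelihood_, abs=1e-5)

    def test_binary_covariate_exponential_closed_form(self):
        # two groups with hazards lambda and 2*lambda: beta -> log 2
        r = np.random.default_rng(8)
        n = 5000
        x = r.binomial(1, 0.5, n).astype(float)
        t = r.exponential(1 / (0.3 * 2**x))
        res = cox_newton(x[:, None], np.zeros(n), t, np.ones(n, dtype=int))
        assert res.beta[0] == pytest.approx(np.log(2), abs=0.05)

    def test_no_events_rejected(self):
        with pytest.raises(NoEventsError):
            cox_newton(np.ones((4, 1)) * [[0], [1], [0], [1]],
                       np.zeros(4), np.ones(4), np.zeros(4, dtype=int))

    def test_constant_covariate_rejected(self):
        with pytest.raises(SeparationError):
            cox_newton(np.ones((10, 1)), np.zeros(10), np.arange(1, 11),
                       np.ones(10, dtype=int))

    def test_delayed_entry_risk_sets(self):
        # episode-split data must reproduce the unsplit fit exactly
        r = np.random.default_rng(5)
        n = 300
        x = r.normal(size=(n, 1))
        t = r.exponential(1 / (0.2 * np.exp(0.5 * x[:, 0])))
        e = np.ones(n, dtype=int)
        base = cox_newton(x, np.zeros(n), t, e)
        cuts = np.unique(t[e == 1])[::5]
        s, st, ev, xs, _ = episode_split(np.zeros(n), t, e, x, cuts)
        split = cox_newton(xs, s, st, ev)
        assert split.beta[0] == pytest.approx(base.beta[0], abs=1e-9)
        assert split.loglik == pytest.approx(base.loglik, abs=1e-8)


class TestLogistic:
    def test_null_marker_or_near_one(self):
        cohort = cohort_with_status(5000, 1, marker_or_cr=1.0)
        fit = logistic_fit(cohort, ModelSpec("cr", ("marker",)))
        assert 0.85 <= fit.ratio("marker") <= 1.18
        assert fit.ratio_label == "OR"

    def test_planted_odds_ratio_recovered(self):
        # the generator plants the training-cohort marker effect (aOR 3.08
        # for induction failure); the fitted OR recovers it
        ors = []
        for seed in range(15):
            cohort = cohort_with_status(20_000, 100 + seed)  # default OR 3.08
            fit = logistic_fit(cohort, ModelSpec("cr", ("marker",)))
            ors.append(fit.ratio("marker"))
        assert np.mean(ors) == pytest.approx(3.08, rel=0.10)

    def test_adjusted_model_runs_with_full_covariates(self):
        cohort = cohort_with_status(2000, 3)
        fit = logistic_fit(cohort, ModelSpec.standard("cr"))
        terms = set(fit.table["term"])
        assert {"marker", "age_per_decade", "age_per_decade_sq",
                "npm1_x_flt3_itd"} <= terms
        assert "age" in fit.joint_tests
        # Wald CI contains the point estimate
        t = fit.table.set_index("term")
        assert (t["ci_low"] <= t["ratio"]).all() and (t["ratio"] <= t["ci_high"]).all()

    @pytest.mark.filterwarnings("ignore::UserWarning")
    def test_separation_detected(self):
        cohort = cohort_with_status(200, 4)
        # a covariate that perfectly predicts failure
        cohort.data["tp53"] = 1 - cohort.data["cr_achieved"]
        with pytest.raises(SeparationError):
            logistic_fit(cohort, ModelSpec("cr", ("marker", "tp53")))


class TestCoxFit:
    def test_planted_death_hazard_recovered(self):
        # no confounding: CR and relapse unaffected by the marker
        hrs = []
        for seed in range(15):
            cohort = cohort_with_status(
                10_000, 200 + seed, marker_or_cr=1.0, marker_hr_relapse=1.0
            )  # default HR death 1.68
            fit = cox_fit(cohort, ModelSpec("os", ("marker",)))
            hrs.append(fit.ratio("marker"))
        assert np.mean(hrs) == pytest.approx(1.68, rel=0.10)

    def test_hsct_time_dependent_column_present(self):
        cohort = cohort_with_status(800, 5)
        fit = cox_fit(cohort, ModelSpec.standard("os"))
        assert "hsct" in set(fit.table["term"])

    def test_rfs_uses_cr_cohort_only(self):
        cohort = cohort_with_status(600, 6)
        fit = cox_fit(cohort, ModelSpec("rfs", ("marker",)))
        assert fit.n_used == int(cohort.data["cr_achieved"].sum())

    def test_hsct_confounding_changes_marker_hr(self):
        # HSCT assigned preferentially to marker-low patients and protective:
        # omitting the time-dependent HSCT term inflates the marker HR
        r = np.random.default_rng(9)
        n = 4000
        marker = r.binomial(1, 0.3, n)
        hsct_time = np.where(
            r.random(n) < np.where(marker == 1, 0.1, 0.6), r.uniform(50, 300, n), np.inf
        )
        lam0, hr_m, hr_h = 1 / 1500, 1.5, 0.4
        t = np.empty(n)
        for i in range(n):
            lam = lam0 * hr_m ** marker[i]
            t1 = r.exponential(1 / lam)
            if t1 <= hsct_time[i]:
                t[i] = t1
            else:
                t[i] = hsct_time[i] + r.exponential(1 / (lam * hr_h))
        e = np.ones(n, dtype=int)
        # with the switching covariate
        rows = []
        for i in range(n):
            if hsct_time[i] < t[i]:
                rows.append((0.0, hsct_time[i], 0, marker[i], 0.0))
                rows.append((hsct_time[i], t[i], 1, marker[i], 1.0))
            else:
                rows.append((0.0, t[i], 1, marker[i], 0.0))
        arr = np.array(rows)
        adj = cox_newton(arr[:, 3:], arr[:, 0], arr[:, 1], arr[:, 2].astype(int))
        unadj = cox_newton(marker[:, None].astype(float), np.zeros(n), t, e)
        assert np.exp(adj.beta[0]) == pytest.approx(hr_m, rel=0.12)
        assert np.exp(unadj.beta[0]) > np.exp(adj.beta[0])  # confounded upward


class TestLunnMcNeil:
    def test_cause_specific_hazards_recovered(self):
        rels, dths = [], []
        for seed in range(10):
            cohort = cohort_with_status(
                10_000, 300 + seed, prevalence=0.3,
                marker_or_cr=1.0, marker_hr_relapse=2.0, marker_hr_death=1.0,
            )
            lm = lunn_mcneil_fit(cohort, ModelSpec("cir-relapse", ("marker",)))
            rels.append(lm[1].ratio("marker"))
            dths.append(lm[2].ratio("marker"))
        assert np.mean(rels) == pytest.approx(2.0, rel=0.10)
        assert np.mean(dths) == pytest.approx(1.0, rel=0.10)

    def test_equals_separate_cause_specific_fits(self):
        from lifelines import CoxPHFitter

        cohort = cohort_with_status(500, 7, prevalence=0.3)
        lm = lunn_mcneil_fit(cohort, ModelSpec("cir-relapse", ("marker",)))
        eps = mp.build_endpoints(cohort, origin="cr")
        d = cohort.data.set_index("patient_id").loc[eps.cir.index]
        marker = (d["marker_status"] == "H+").astype(float)
        for cause in (1, 2):
            df = pd.DataFrame(
                {
                    "T": np.maximum(eps.cir["time"].to_numpy(), 0.5),
                    "E": (eps.cir["cause"] == cause).astype(int).to_numpy(),
                    "marker": marker.to_numpy(),
                }
            )
            ref = CoxPHFitter().fit(df, "T", "E")
            assert lm[cause].table.set_index("term").loc["marker", "coef"] == (
                pytest.approx(ref.params_["marker"], abs=1e-4)
            )

    def test_single_cause_reduces_to_plain_cox(self):
        cohort = cohort_with_status(400, 8, prevalence=0.3)
        # remove relapses: every failure becomes death-without-relapse
        cohort.data["relapse_day"] = np.nan
        lm = lunn_mcneil_fit(cohort, ModelSpec("cir-relapse", ("marker",)))
        assert 1 not in lm  # no relapse events left
        eps = mp.build_endpoints(cohort, origin="cr")
        d = cohort.data.set_index("patient_id").loc[eps.cir.index]
        res = cox_newton(
            (d["marker_status"] == "H+").to_numpy(dtype=float)[:, None],
            np.zeros(len(d)),
            np.maximum(eps.cir["time"].to_numpy(), 0.5),
            (eps.cir["cause"] == 2).astype(int).to_numpy(),
        )
        assert lm[2].table.loc[0, "coef"] == pytest.approx(res.beta[0], abs=1e-8)

    def test_null_marker_cis_cover_one(self):
        covered = 0
        n_rep = 40
        for seed in range(n_rep):
            cohort = cohort_with_status(
                600, 500 + seed, prevalence=0.3,
                marker_or_cr=1.0, marker_hr_relapse=1.0, marker_hr_death=1.0,
            )
            lm = lunn_mcneil_fit(cohort, ModelSpec("cir-relapse", ("marker",)))
            t = lm[1].table.set_index("term").loc["marker"]
            covered += t["ci_low"] <= 1.0 <= t["ci_high"]
        # ~95% coverage; binomial 3-sigma band around 0.95 of 40
        assert covered >= 33


class TestPhTest:
    def test_null_p_not_small(self):
        cohort = cohort_with_status(500, 11)
        p = ph_test(cohort, ModelSpec("os", ("marker",)))
        assert 0.0 <= p["marker"] <= 1.0

    def test_crossing_hazards_detected(self):
        # effect +beta before t0 and -beta after: strong PH violation
        hits = 0
        n_rep = 20
        for seed in range(n_rep):
            r = np.random.default_rng(seed)
            n = 1000
            x = r.binomial(1, 0.5, n).astype(float)
            t0, lam, b = 1.0, 0.5, 1.2
            lam1 = lam * np.exp(b * x)
            t1 = r.exponential(1 / lam1)
            lam2 = lam * np.exp(-b * x)
            t = np.where(t1 <= t0, t1, t0 + r.exponential(1 / lam2))
            base = cox_newton(x[:, None], np.zeros(n), t, np.ones(n, dtype=int))
            ev_times = np.unique(t)
            s, st, ev, xs, _ = episode_split(
                np.zeros(n), t, np.ones(n, dtype=int), x[:, None], ev_times
            )
            logt = np.log(st)[:, None] - np.mean(np.log(st))
            ext = cox_newton(
                np.column_stack([xs, logt * xs]), s, st, ev
            )
            from scipy.stats import chi2

            lrt = 2 * (ext.loglik - base.loglik)
            hits += chi2.sf(lrt, 1) < 0.05
        assert hits / n_rep > 0.8

    def test_ph_test_via_module_interface_detects_violation(self):
        # build a cohort whose marker effect reverses over time
        r = np.random.default_rng(21)
        n = 1200
        cohort = cohort_with_status(n, 12, prevalence=0.5,
                                    marker_hr_death=1.0, marker_hr_relapse=1.0,
                                    marker_or_cr=1.0, censoring_rate=0.0)
        d = cohort.data
        x = (d["marker_status"] == "H+").to_numpy()
        t0, lam, b = 400.0, 1 / 1200, 1.3
        t1 = r.exponential(1 / (lam * np.exp(b * x)))
        t = np.where(t1 <= t0, t1, t0 + r.exponential(1 / (lam * np.exp(-b * x))))
        d["cr_achieved"] = 0
        d["cr_day"] = np.nan
        d["relapse_day"] = np.nan
        d["hsct_day"] = np.nan
        d["death_day"] = t
        d["last_followup_day"] = t
        p = ph_test(cohort, ModelSpec("os", ("marker",)))
        assert p["marker"] < 0.05

    def test_unknown_covariate_rejected(self):
        cohort = cohort_with_status(300, 13)
        with pytest.raises(InvalidInputError):
            ph_test(cohort, ModelSpec("os", ("marker",)), covariates=["wbc_log"])
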