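"""Cox models, cutpoints, KM/log-rank, C-index, td-AUC, nomogram, DCA, PH."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from stromaquant import survival as surv
from stromaquant.simulate import SurvivalCohortSpec, gen_survival_cohort


def cox_partial_loglik_1d(beta: float, time, event, x) -> float:
    """Independent oracle: 1-covariate Efron partial log-likelihood."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    x = np.asarray(x, dtype=float)
    ll = 0.0
    for t in np.unique(time[event == 1]):
        d_idx = np.flatnonzero((time == t) & (event == 1))
        r_idx = np.flatnonzero(time >= t)
        d = len(d_idx)
        theta_r = np.exp(beta * x[r_idx]).sum()
        theta_d = np.exp(beta * x[d_idx]).sum()
        ll += beta * x[d_idx].sum()
        for j in range(d):
            ll -= np.log(theta_r - j / d * theta_d)
    return ll


def brute_force_cindex(time, event, risk) -> float:
    """Exhaustive pair enumeration; ties in risk count one half."""
    conc = disc = ties = 0
    n = len(time)
    for i, j in itertools.combinations(range(n), 2):
        if time[i] == time[j]:
            continue
        first, second = (i, j) if time[i] < time[j] else (j, i)
        if not event[first]:
            continue  # earlier time censored: unusable pair
        if risk[first] > risk[second]:
            conc += 1
        elif risk[first] < risk[second]:
            disc += 1
        else:
            ties += 1
    return (conc + 0.5 * ties) / (conc + disc + ties)


@pytest.fixture(scope="module")
def toy_records():
    return pd.DataFrame(
        {
            "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "event": [1, 1, 0, 1, 1, 1],
            "x": [2.1, 0.4, 1.5, 0.9, -0.3, -1.1],
        }
    )


class TestCox:
    def test_beta_matches_grid_search_oracle(self, toy_records):
        fit = surv.fit_cox(toy_records, ["x"])
        res = minimize_scalar(
            lambda b: -cox_partial_loglik_1d(
                b, toy_records["time"], toy_records["event"], toy_records["x"]
            ),
            bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-6},
        )
        assert fit.beta["x"] == pytest.approx(res.x, abs=1e-3)

    def test_null_covariate_rarely_three_sigma(self):
        hits = 0
        reps = 40
        for i in range(reps):
            df = gen_survival_cohort(
                SurvivalCohortSpec(n_subjects=1000, baseline_hazard=0.05,
                                   censoring_rate=0.02, seed=300 + i)
            )
            fit = surv.fit_cox(df, ["mtsr"])
            hits += int(abs(fit.beta["mtsr"]) < 3 * fit.se["mtsr"])
        assert hits / reps >= 0.95

    def test_ci_and_hr_consistent(self, toy_records):
        fit = surv.fit_cox(toy_records, ["x"])
        assert fit.ci_lower["x"] == pytest.approx(
            np.exp(fit.beta["x"] - surv.Z95 * fit.se["x"])
        )
        assert fit.hr["x"] > 0

    def test_no_events_rejected(self):
        df = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [0, 0, 0], "x": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            surv.fit_cox(df, ["x"])

    def test_separation_flagged_not_silent(self):
        # perfectly separating covariate: monotone likelihood
        df = pd.DataFrame(
            {"time": [1, 2, 3, 4, 5, 6, 7, 8.0],
             "event": [1, 1, 1, 1, 0, 0, 1, 1],
             "x": [10.0, 9.0, 8.0, 7.0, 1.0, 1.5, 0.5, 0.1]}
        )
        fit = surv.fit_cox(df, ["x"])
        assert fit.hr["x"] > 0  # still returns a usable (penalized) result


class TestMaxstat:
    def test_planted_step_recovered(self):
        hits = 0
        for i in range(5):
            rng = np.random.default_rng(500 + i)
            n = 300
            x = rng.uniform(0, 20, n)
            hr = np.where(x > 10, 3.0, 1.0)
            t_event = rng.exponential(1.0 / (0.05 * hr))
            t_cens = rng.exponential(40.0, n)
            df = pd.DataFrame(
                {"time": np.minimum(t_event, t_cens),
                 "event": (t_event <= t_cens).astype(int), "x": x}
            )
            res = surv.maxstat_cutpoint(df, "x", n_perm=19, seed=i)
            hits += int(8.0 <= res.cutoff <= 12.0)
        assert hits >= 4

    def test_constant_covariate_rejected(self):
        df = pd.DataFrame({"time": np.arange(1, 21, dtype=float),
                           "event": np.ones(20, dtype=int), "x": np.full(20, 5.0)})
        with pytest.raises(ValueError):
            surv.maxstat_cutpoint(df, "x", n_perm=10)

    def test_cutoff_inside_candidate_range(self):
        df = gen_survival_cohort(SurvivalCohortSpec(n_subjects=80, seed=3))
        res = surv.maxstat_cutpoint(df, "mtsr", n_perm=19, seed=0)
        lo, hi = res.candidate_range
        assert lo <= res.cutoff <= hi

    def test_null_permutation_p_is_uniform(self):
        """Adjusted p-values under a null covariate are uniform on (0, 1]."""
        from scipy.stats import kstest

        ps = []
        for i in range(60):
            df = gen_survival_cohort(
                SurvivalCohortSpec(n_subjects=60, baseline_hazard=0.05,
                                   censoring_rate=0.02, seed=700 + i)
            )
            res = surv.maxstat_cutpoint(df, "mtsr", n_perm=49, seed=i)
            ps.append(res.p_value)
        assert kstest(ps, "uniform").pvalue > 0.01


class TestKMLogrank:
    def test_identical_groups_give_zero_chi2(self):
        df = gen_survival_cohort(SurvivalCohortSpec(n_subjects=40, seed=5))
        doubled = pd.concat([df, df], ignore_index=True)
        group = np.repeat([0, 1], len(df))
        res = surv.km_logrank(doubled, group)
        assert res.chi2 == pytest.approx(0.0, abs=1e-10)

    def test_km_median_equals_sample_median_without_censoring(self):
        from lifelines import KaplanMeierFitter

        df = gen_survival_cohort(
            SurvivalCohortSpec(n_subjects=101, censoring_rate=0.0, seed=6)
        )
        kmf = KaplanMeierFitter().fit(df["time"], df["event"])
        assert kmf.median_survival_time_ == pytest.approx(float(np.median(df["time"])))

    def test_hand_table_matches_manual_oe_v_sum(self):
        # 5 subjects per group, all events, distinct times
        df = pd.DataFrame(
            {"time": [1, 3, 5, 7, 9, 2, 4, 6, 8, 10.0],
             "event": [1] * 10,
             "g": [0] * 5 + [1] * 5}
        )
        # manual O-E and V accumulation over event times
        o_minus_e = 0.0
        var = 0.0
        for t in sorted(df["time"]):
            at_risk = df[df["time"] >= t]
            d = int((df["time"] == t).sum())
            n = len(at_risk)
            n1 = int((at_risk["g"] == 1).sum())
            d1 = int(((df["time"] == t) & (df["g"] == 1)).sum())
            if n > 1:
                o_minus_e += d1 - d * n1 / n
                var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        expected_chi2 = o_minus_e**2 / var
        res = surv.km_logrank(df, df["g"].to_numpy())
        assert res.chi2 == pytest.approx(expected_chi2, abs=1e-10)
        z = surv.logrank_statistic(df["time"].to_numpy(), df["event"].to_numpy(),
                                   df["g"].to_numpy() == 1)
        assert z**2 == pytest.approx(expected_chi2, abs=1e-10)


class TestConcordance:
    def test_perfectly_antiranked_risk_is_one(self):
        df = pd.DataFrame({"time": np.arange(1, 11, dtype=float), "event": np.ones(10, dtype=int)})
        risk = 10 - np.arange(10, dtype=float)  # earliest failure has highest risk
        assert surv.concordance_index(df, risk) == 1.0

    def test_null_risk_near_half(self):
        rng = np.random.default_rng(9)
        df = gen_survival_cohort(SurvivalCohortSpec(n_subjects=3000, seed=9))
        c = surv.concordance_index(df, rng.normal(size=len(df)))
        assert abs(c - 0.5) < 0.02

    def test_matches_brute_force_with_censoring(self):
        rng = np.random.default_rng(12)
        for rep in range(10):
            n = rng.integers(5, 21)
            df = pd.DataFrame(
                {"time": rng.permutation(np.arange(1, n + 1, dtype=float)),
                 "event": rng.integers(0, 2, n)}
            )
            if df["event"].sum() == 0:
                continue
            risk = rng.choice(np.arange(5), size=n).astype(float)  # forces risk ties
            expected = brute_force_cindex(
                df["time"].to_numpy(), df["event"].to_numpy(), risk
            )
            assert surv.concordance_index(df, risk) == pytest.approx(expected, abs=1e-12)


class TestTimeDependentAUC:
    def test_perfect_marker_reaches_one(self):
        n = 60
        time = np.linspace(1, 12, n)
        df = pd.DataFrame({"time": time, "event": np.ones(n, dtype=int)})
        risk = -time  # earlier failure = higher risk
        aucs = surv.time_dependent_auc(df, risk, [3.0, 5.0, 8.0])
        for v in aucs.values():
            assert v == pytest.approx(1.0)

    def test_null_marker_near_half(self):
        rng = np.random.default_rng(21)
        df = gen_survival_cohort(SurvivalCohortSpec(n_subjects=2000, seed=21))
        aucs = surv.time_dependent_auc(df, rng.normal(size=len(df)), [10.0])
        assert abs(aucs[10.0] - 0.5) < 0.05

    def test_reduces_to_binary_auc_without_censoring(self):
        from sklearn.metrics import roc_auc_score

        df = gen_survival_cohort(
            SurvivalCohortSpec(n_subjects=300, censoring_rate=0.0,
                               beta_mtsr=0.05, baseline_hazard=0.05, seed=22)
        )
        risk = df["mtsr"].to_numpy()
        horizon = float(np.median(df["time"]))
        aucs = surv.time_dependent_auc(df, risk, [horizon])
        binary = roc_auc_score((df["time"] <= horizon).astype(int), risk)
        assert aucs[horizon] == pytest.approx(binary, abs=1e-9)

    def test_horizon_beyond_followup_reported_undefined(self):
        df = gen_survival_cohort(SurvivalCohortSpec(n_subjects=50, seed=23))
        aucs = surv.time_dependent_auc(df, df["mtsr"].to_numpy(), [1e9])
        assert np.isnan(aucs[1e9])


@pytest.fixture(scope="module")
def planted_fit():
    df = gen_survival_cohort(
        SurvivalCohortSpec(
            n_subjects=400, baseline_hazard=0.2, beta_mtsr=float(np.log(1.5) / 10),
            beta_nstage=float(np.log(1.8)), censoring_rate=0.05, seed=31,
        )
    )
    return surv.fit_cox(df, ["mtsr", "nstage"]), df


class TestNomogram:
    def test_points_predictions_match_direct_cox_survival(self, planted_fit):
        fit, df = planted_fit
        model = surv.build_nomogram(fit, [1.0, 3.0, 5.0])
        via_points = surv.predict_nomogram(model, df)
        sf = fit.model.predict_survival_function(fit.data)
        for t in (1.0, 3.0, 5.0):
            idx = sf.index[sf.index <= t]
            direct = sf.loc[idx[-1]].to_numpy() if len(idx) else np.ones(len(df))
            np.testing.assert_allclose(via_points[t].to_numpy(), direct, atol=1e-9)

    def test_zero_betas_give_identical_predictions(self, planted_fit):
        fit, df = planted_fit
        model = surv.build_nomogram(fit, [3.0])
        flat = surv.NomogramModel(
            covariates=model.covariates,
            beta=pd.Series(0.0, index=list(model.covariates)),
            ref=model.ref, cov_range=model.cov_range,
            points_per_lp=model.points_per_lp, mean_lp=0.0,
            baseline_survival=model.baseline_survival, horizons=model.horizons,
        )
        pred = surv.predict_nomogram(flat, df)
        assert pred[3.0].nunique() == 1

    def test_survival_decreases_with_mtsr(self, planted_fit):
        fit, _ = planted_fit
        model = surv.build_nomogram(fit, [3.0])
        probe = pd.DataFrame({"mtsr": [5.0, 15.0, 30.0], "nstage": [0, 0, 0]})
        pred = surv.predict_nomogram(model, probe)[3.0].to_numpy()
        assert pred[0] > pred[1] > pred[2]

    def test_points_are_nonnegative_and_span_at_most_100(self, planted_fit):
        fit, df = planted_fit
        model = surv.build_nomogram(fit, [3.0])
        pts = model.points(df)
        for c in model.covariates:
            assert pts[c].min() >= -1e-9
            assert pts[c].max() <= 100 + 1e-9


class TestCalibration:
    def test_self_generated_data_calibrates_near_unity(self):
        df = gen_survival_cohort(
            SurvivalCohortSpec(n_subjects=1000, baseline_hazard=0.2,
                               beta_mtsr=float(np.log(1.5) / 10),
                               beta_nstage=0.6, censoring_rate=0.05, seed=41)
        )
        fit = surv.fit_cox(df, ["mtsr", "nstage"])
        out = surv.calibration_bootstrap(fit, [3.0], n_boot=40, seed=1)
        assert 0.9 <= out["slope_corrected"] <= 1.1

    def test_zero_bootstrap_returns_flagged_apparent_curve(self, planted_fit):
        fit, _ = planted_fit
        out = surv.calibration_bootstrap(fit, [3.0], n_boot=0)
        assert out["apparent_only"]
        assert out["slope_corrected"] is None

    def test_one_row_per_decile_group(self, planted_fit):
        fit, _ = planted_fit
        out = surv.calibration_bootstrap(fit, [1.0, 3.0], n_boot=0)
        counts = out["table"].groupby("horizon").size()
        assert (counts == 10).all()


class TestDecisionCurve:
    @pytest.fixture(scope="class")
    def uncensored(self):
        df = gen_survival_cohort(
            SurvivalCohortSpec(n_subjects=400, censoring_rate=0.0,
                               baseline_hazard=0.1, seed=51)
        )
        return df

    def test_treat_none_is_zero(self, uncensored):
        out = surv.decision_curve(uncensored, {}, horizon=5.0, thresholds=np.array([0.2, 0.5]))
        nb = out[out["model"] == "treat_none"]["net_benefit"]
        assert (nb == 0).all()

    def test_treat_all_matches_closed_form_without_censoring(self, uncensored):
        horizon = 5.0
        prevalence = (uncensored["time"] <= horizon).mean()
        out = surv.decision_curve(uncensored, {}, horizon, thresholds=np.array([0.1, 0.3, 0.6]))
        for _, row in out[out["model"] == "treat_all"].iterrows():
            pt = row["threshold"]
            expected = prevalence - (1 - prevalence) * pt / (1 - pt)
            assert row["net_benefit"] == pytest.approx(expected, abs=1e-9)

    def test_perfect_predictor_net_benefit_equals_prevalence(self, uncensored):
        horizon = 5.0
        event_by_t = (uncensored["time"] <= horizon).astype(float)
        prevalence = event_by_t.mean()
        out = surv.decision_curve(
            uncensored, {"oracle": event_by_t.to_numpy()}, horizon,
            thresholds=np.array([0.1, 0.4, 0.8]),
        )
        for _, row in out[out["model"] == "oracle"].iterrows():
            assert row["net_benefit"] == pytest.approx(prevalence, abs=1e-9)


class TestSchoenfeld:
    def test_one_p_per_covariate_plus_global(self, planted_fit):
        fit, _ = planted_fit
        out = surv.schoenfeld_test(fit)
        assert list(out["covariate"]) == ["mtsr", "nstage", "GLOBAL"]
        assert out["p"].between(0, 1).all()

    def test_agrees_with_r_style_reference_decision(self, planted_fit):
        """lifelines' own rank-transform PH test should broadly agree."""
        from lifelines.statistics import proportional_hazard_test

        fit, _ = planted_fit
        ours = surv.schoenfeld_test(fit).set_index("covariate")
        ref = proportional_hazard_test(fit.model, fit.data, time_transform="rank")
        for cov in ("mtsr", "nstage"):
            assert abs(ours.loc[cov, "p"] - ref.summary.loc[cov, "p"]) < 0.2

    def test_null_rejection_rate_near_alpha(self):
        """Constant-HR simulations keep the per-covariate rejection rate at
        its nominal 5% level (500 replicates)."""
        rej = 0
        reps = 500
        for i in range(reps):
            df = gen_survival_cohort(
                SurvivalCohortSpec(n_subjects=120, baseline_hazard=0.08,
                                   beta_mtsr=0.03, censoring_rate=0.02, seed=900 + i)
            )
            fit = surv.fit_cox(df, ["mtsr"])
            ph = surv.schoenfeld_test(fit)
            rej += int(ph.loc[ph["covariate"] == "mtsr", "p"].iloc[0] < 0.05)
        assert 0.03 <= rej / reps <= 0.07
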