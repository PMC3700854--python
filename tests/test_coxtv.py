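"""Partial-likelihood engine: closed forms, oracle equivalence, reductions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ildcox as ic
from ildcox import coxtv

from _oracles import brute_force_logpl


class TestLogPartialLikelihood:
    def test_null_coefficient_closed_form(self, three_subject_intervals):
        # risk sets of sizes 3 then 2
        ll = ic.log_partial_likelihood(three_subject_intervals, {"z": 0.0})
        assert ll == pytest.approx(-np.log(3) - np.log(2), abs=1e-12)

    def test_closed_form_at_mle_argument(self, three_subject_intervals):
        b = -0.5 * np.log(2)
        expected = b - np.log(2 * np.exp(b) + 1) - np.log(np.exp(b) + 1)
        ll = ic.log_partial_likelihood(three_subject_intervals, {"z": b})
        assert ll == pytest.approx(expected, abs=1e-12)

    def test_left_truncated_subject_outside_early_risk_set(
        self, three_subject_intervals
    ):
        # a subject entering at t=2 cannot sit in the risk set of the t=1 event
        only_first = three_subject_intervals.iloc[[0]]
        extra = pd.DataFrame(
            {
                "id": ["D"],
                "transition": ["13"],
                "start": [2.0],
                "stop": [3.0],
                "status": [0],
                "z": [5.0],
            }
        )
        ll0 = ic.log_partial_likelihood(only_first, {"z": 0.3})
        ll1 = ic.log_partial_likelihood(pd.concat([only_first, extra]), {"z": 0.3})
        assert ll1 == pytest.approx(ll0, abs=1e-14)

    def test_no_events_is_an_error(self):
        df = pd.DataFrame(
            {"id": [1], "transition": ["13"], "start": [0.0], "stop": [1.0],
             "status": [0], "z": [1.0]}
        )
        with pytest.raises(coxtv.CoxError, match="no events"):
            ic.log_partial_likelihood(df, {"z": 0.0})

    @given(
        data=st.lists(
            st.tuples(
                st.floats(0.05, 10.0),  # stop offsets
                st.integers(0, 1),  # status
                st.floats(-2.0, 2.0),  # z1
                st.floats(-2.0, 2.0),  # z2
                st.floats(0.0, 0.9),  # entry fraction of stop
            ),
            min_size=2,
            max_size=6,
        ),
        beta=st.tuples(st.floats(-1.5, 1.5), st.floats(-1.5, 1.5)),
    )
    def test_matches_brute_force_enumeration(self, data, beta):
        rows = []
        for i, (stop, status, z1, z2, frac) in enumerate(data):
            rows.append(
                {"id": i, "transition": "13", "start": stop * frac, "stop": stop,
                 "status": status, "z1": z1, "z2": z2}
            )
        df = pd.DataFrame(rows)
        if int(df["status"].sum()) == 0:
            df.loc[0, "status"] = 1
        for ties in ("efron", "breslow"):
            mine = ic.log_partial_likelihood(
                df, list(beta), covariates=["z1", "z2"], ties_method=ties
            )
            oracle = brute_force_logpl(df, ["z1", "z2"], beta, ties=ties)
            assert mine == pytest.approx(oracle, abs=1e-10)

    def test_ties_against_brute_force(self):
        # three events share t=2; Efron and Breslow must both match the oracle
        df = pd.DataFrame(
            {
                "id": range(6),
                "transition": ["13"] * 6,
                "start": 0.0,
                "stop": [1.0, 2.0, 2.0, 2.0, 3.0, 4.0],
                "status": [1, 1, 1, 1, 0, 1],
                "z": [0.5, -1.0, 0.0, 1.0, 2.0, -0.5],
            }
        )
        for ties in ("efron", "breslow"):
            mine = ic.log_partial_likelihood(df, [0.7], ["z"], ties_method=ties)
            assert mine == pytest.approx(
                brute_force_logpl(df, ["z"], [0.7], ties), abs=1e-10
            )
        assert ic.log_partial_likelihood(df, [0.7], ["z"], "efron") != pytest.approx(
            ic.log_partial_likelihood(df, [0.7], ["z"], "breslow"), abs=1e-6
        )


class TestFitCox:
    def test_three_subject_mle_closed_form(self, three_subject_intervals):
        fit = ic.fit_cox(three_subject_intervals, ["z"])
        assert fit.converged
        assert fit.coefficients[0] == pytest.approx(-0.5 * np.log(2), abs=1e-7)
        assert fit.aic == pytest.approx(-2 * fit.log_pl + 2, abs=1e-12)

    def test_null_model_loglik_is_sum_of_log_risk_sizes(self, three_subject_intervals):
        fit = ic.fit_cox(three_subject_intervals, [])
        assert fit.k == 0
        assert fit.log_pl == pytest.approx(-np.log(3) - np.log(2), abs=1e-12)
        assert fit.aic == pytest.approx(-2 * fit.log_pl, abs=1e-12)

    def test_monotone_likelihood_is_flagged(self):
        # perfectly separating covariate: partial likelihood increasing in beta
        df = pd.DataFrame(
            {"id": [1, 2], "transition": ["13"] * 2, "start": 0.0,
             "stop": [1.0, 2.0], "status": [1, 1], "z": [1.0, 0.0]}
        )
        with pytest.warns(RuntimeWarning, match="did not converge"):
            fit = ic.fit_cox(df, ["z"])
        assert not fit.converged
        assert "z" in fit.message

    def test_rank_deficiency_names_collinear_columns(self, three_subject_intervals):
        df = three_subject_intervals.assign(z_copy=lambda x: 2.0 * x["z"])
        with pytest.raises(coxtv.CoxError, match="collinear"):
            ic.fit_cox(df, ["z", "z_copy"])

    def test_loglik_invariant_to_splitting_at_non_event_time(
        self, three_subject_intervals
    ):
        df = three_subject_intervals
        split = pd.concat(
            [
                df.iloc[[0, 1]],
                pd.DataFrame(
                    {"id": ["C", "C"], "transition": ["13"] * 2,
                     "start": [0.0, 1.7], "stop": [1.7, 3.0],
                     "status": [0, 0], "z": [1.0, 1.0]}
                ),
            ],
            ignore_index=True,
        )
        f0 = ic.fit_cox(df, ["z"])
        f1 = ic.fit_cox(split, ["z"])
        assert f1.log_pl == pytest.approx(f0.log_pl, abs=1e-10)
        assert f1.coefficients[0] == pytest.approx(f0.coefficients[0], abs=1e-8)

    def test_agrees_with_lifelines_on_time_varying_data(self, exp_decay_cohort):
        lifelines = pytest.importorskip("lifelines")
        tab, _ = exp_decay_cohort
        layout, _ = ic.to_joint_layout(
            tab, [ic.INDICATOR, ic.D_LINEAR, ic.EXP_NEG_SOJOURN]
        )
        covs = ["in_state_2", "onset_time", "exp_neg_sojourn", "z_cont", "z_bin"]
        mine = ic.fit_cox(layout, covs)
        ctv = lifelines.CoxTimeVaryingFitter(penalizer=0.0)
        ll_df = layout[["id", "start", "stop", "status"] + covs].copy()
        ctv.fit(ll_df, id_col="id", start_col="start", stop_col="stop",
                event_col="status")
        theirs = ctv.params_[covs].to_numpy()
        assert np.allclose(mine.coefficients, theirs, atol=5e-4)
        se_theirs = ctv.standard_errors_[covs].to_numpy()
        assert np.allclose(mine.bse.to_numpy(), se_theirs, rtol=5e-3)


class TestBreslowBaseline:
    def test_reduces_to_nelson_aalen_at_beta_zero(self, three_subject_intervals):
        fit = ic.fit_cox(three_subject_intervals, [])
        base = ic.breslow_baseline(fit, three_subject_intervals)
        assert np.allclose(base.increments, [1 / 3, 1 / 2], atol=1e-14)
        assert np.allclose(base.cumulative, [1 / 3, 1 / 3 + 1 / 2], atol=1e-14)

    def test_single_subject_increment(self):
        df = pd.DataFrame(
            {"id": [1], "transition": ["13"], "start": [0.0], "stop": [2.0],
             "status": [1], "z": [0.7]}
        )
        fit = ic.fit_cox(df, [])
        fit2 = coxtv.CoxFit(
            names=["z"], coefficients=np.array([0.5]), covariance=np.eye(1),
            log_pl=0.0, log_pl_null=0.0, k=1, ties_method="efron",
            converged=True, n_iter=0, n_events=1, n_rows=1,
        )
        base = ic.breslow_baseline(fit2, df)
        assert base.increments[0] == pytest.approx(1.0 / np.exp(0.7 * 0.5))

    def test_invariant_under_cohort_replication(self, three_subject_intervals):
        df = three_subject_intervals
        doubled = pd.concat(
            [df, df.assign(id=lambda x: x["id"] + "_copy")], ignore_index=True
        )
        fit = ic.fit_cox(df, ["z"])
        fixed = coxtv.CoxFit(
            names=["z"], coefficients=fit.coefficients, covariance=fit.covariance,
            log_pl=0.0, log_pl_null=0.0, k=1, ties_method="efron",
            converged=True, n_iter=0, n_events=2, n_rows=3,
        )
        b1 = ic.breslow_baseline(fixed, df)
        b2 = ic.breslow_baseline(fixed, doubled)
        assert np.allclose(b1.cumulative, b2.cumulative, atol=1e-12)


class TestLrAndElimination:
    def test_identical_models_give_zero_statistic(self, three_subject_intervals):
        fit = ic.fit_cox(three_subject_intervals, ["z"])
        stat, df_, p = ic.lr_test(fit, fit)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert df_ == 0 and p == 1.0

    def test_chi_square_tail_value(self, three_subject_intervals):
        # the 1% critical value of chi2(1) is 6.635
        full = ic.fit_cox(three_subject_intervals, ["z"])
        nested = ic.fit_cox(three_subject_intervals, [])
        fake_full = coxtv.CoxFit(
            names=["z"], coefficients=full.coefficients, covariance=full.covariance,
            log_pl=nested.log_pl + 6.635 / 2, log_pl_null=nested.log_pl, k=1,
            ties_method="efron", converged=True, n_iter=1, n_events=2, n_rows=3,
        )
        _, df_, p = ic.lr_test(fake_full, nested)
        assert df_ == 1
        assert p == pytest.approx(0.010, abs=5e-4)

    def test_unmaximised_likelihood_is_an_error(self, three_subject_intervals):
        good = ic.fit_cox(three_subject_intervals, ["z"])
        bad = coxtv.CoxFit(
            names=[], coefficients=np.zeros(0), covariance=np.zeros((0, 0)),
            log_pl=good.log_pl + 1.0, log_pl_null=0.0, k=0, ties_method="efron",
            converged=True, n_iter=0, n_events=2, n_rows=3,
        )
        with pytest.raises(coxtv.CoxError, match="not maximised"):
            ic.lr_test(good, bad)

    def test_null_covariate_lr_pvalues_uniform(self):
        # LR p-values for a pure-noise covariate are U(0,1) under the null
        from scipy import stats

        rng = np.random.default_rng(99)
        pvals = []
        for _ in range(200):
            n = 80
            z = rng.standard_normal(n)
            t = rng.exponential(1.0, n)
            df = pd.DataFrame(
                {"id": range(n), "transition": "13", "start": 0.0,
                 "stop": np.minimum(t, 2.5), "status": (t <= 2.5).astype(int),
                 "z": z}
            )
            full = ic.fit_cox(df, ["z"])
            nested = ic.fit_cox(df, [])
            pvals.append(ic.lr_test(full, nested)[2])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_alpha_one_retains_everything(self, three_subject_intervals):
        retained, fit = ic.backward_eliminate(
            three_subject_intervals, ["z"], alpha=1.0
        )
        assert retained == ["z"]
        assert fit.k == 1

    def test_no_candidates_yields_null_model(self, three_subject_intervals):
        retained, fit = ic.backward_eliminate(three_subject_intervals, [], alpha=0.01)
        assert retained == [] and fit.k == 0

    def test_retains_strong_effect_drops_noise(self):
        # simulated cohort with one real log-hazard ratio of 1 and one null
        rng = np.random.default_rng(12)
        n = 800
        z_strong = rng.standard_normal(n)
        z_null = rng.standard_normal(n)
        t = rng.exponential(1.0 / (0.5 * np.exp(1.0 * z_strong)))
        cens = np.minimum(rng.exponential(4.0, n), 3.0)
        df = pd.DataFrame(
            {
                "id": range(n), "transition": "13", "start": 0.0,
                "stop": np.minimum(t, cens), "status": (t <= cens).astype(int),
                "z_strong": z_strong, "z_null": z_null,
            }
        )
        retained, _ = ic.backward_eliminate(df, ["z_strong", "z_null"], alpha=0.01)
        assert retained == ["z_strong"]
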