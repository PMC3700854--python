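"""Joint/separate model families, smoothing, surfaces, AIC comparison."""

import numpy as np
import pandas as pd
import pytest

import ildcox as ic
from ildcox.coxtv import BaselineHazard, CoxError
from ildcox.fracpoly import FPTransform
from ildcox.models import (
    build_relation,
    compare_models,
    fit_joint,
    fit_separate,
    smooth_hazard,
)


class TestBuildRelation:
    @pytest.mark.parametrize(
        "relation,expected_cols",
        [
            ("J.I", []),
            ("J.II", ["in_state_2"]),
            ("J.III.1", ["in_state_2", "onset_time"]),
            ("J.III.2", ["in_state_2", "exp_neg_sojourn"]),
            ("J.IV", ["in_state_2", "onset_time", "exp_neg_sojourn"]),
        ],
    )
    def test_term_sets_of_the_relation_family(self, relation, expected_cols):
        terms = build_relation(relation)
        assert ic.restructure.term_columns(terms) == expected_cols

    def test_fp_relation_terms(self):
        terms = build_relation("J.FP", FPTransform((-1.0,)))
        cols = ic.restructure.term_columns(terms)
        assert cols == ["in_state_2", "sojourn_pm1"]
        with_d = build_relation("J.FP", FPTransform((-1.0,)), include_onset=True)
        assert "onset_time" in ic.restructure.term_columns(with_d)

    def test_unknown_relation_rejected(self):
        with pytest.raises(ValueError, match="unknown relation"):
            build_relation("J.V")
        with pytest.raises(ValueError, match="fp_transform"):
            build_relation("J.FP")


class TestJointModel:
    def test_nested_loglik_monotone_along_both_chains(self, exp_decay_cohort):
        tab, _ = exp_decay_cohort
        ll = {
            r: fit_joint(tab, relation=r).llf
            for r in ("J.I", "J.II", "J.III.1", "J.III.2", "J.IV")
        }
        assert ll["J.I"] <= ll["J.II"] + 1e-8
        assert ll["J.II"] <= ll["J.III.1"] + 1e-8
        assert ll["J.II"] <= ll["J.III.2"] + 1e-8
        assert ll["J.III.1"] <= ll["J.IV"] + 1e-8
        assert ll["J.III.2"] <= ll["J.IV"] + 1e-8

    def test_null_effect_gives_unit_relation(self, null_cohort):
        tab, _ = null_cohort
        res = fit_joint(tab, relation="J.II")
        ci = res.fit.confint().loc["in_state_2"]
        assert ci["lower"] < 0.0 < ci["upper"]
        surface = res.c_surface()
        assert np.allclose(surface.values, surface.values[0, 0])

    def test_surface_shape_constraints_per_relation(self, exp_decay_cohort):
        tab, _ = exp_decay_cohort
        for relation, axis in (("J.II", None), ("J.III.1", 1), ("J.III.2", 0)):
            surf = fit_joint(tab, relation=relation).c_surface()
            if axis is None:
                assert np.allclose(surf.values, surf.values[0, 0])
            elif axis == 1:  # constant along sojourn axis
                assert np.allclose(surf.values, surf.values[:, :1])
            else:  # constant along waiting-time axis
                assert np.allclose(surf.values, surf.values[:1, :])

    def test_parameter_recovery_for_exponential_decay_relation(self, exp_decay_cohort):
        tab, truth = exp_decay_cohort
        res = fit_joint(tab, relation="J.IV")
        spec = truth["config"]["c_spec"]
        target = {
            "in_state_2": spec["b0"],
            "onset_time": spec["b1"],
            "exp_neg_sojourn": spec["b2"],
            "z_cont": truth["config"]["gamma13"][0],
            "z_bin": truth["config"]["gamma13"][1],
        }
        for name, value in target.items():
            assert abs(res.params[name] - value) < 3.5 * res.bse[name], name

    def test_summary_mentions_relation_and_both_fits(self, exp_decay_cohort):
        tab, _ = exp_decay_cohort
        text = fit_joint(tab, relation="J.IV").summary()
        assert "J.IV" in text and "1->2" in text and "exp_neg_sojourn" in text


class TestSeparateModel:
    def test_shared_effect_recovered_by_all_transitions(self, null_cohort):
        tab, _ = null_cohort
        res = fit_separate(tab, f_terms=())
        # generated with no covariate effects: all gammas near zero
        for trans in ("12", "13", "23"):
            fit = res.fits[trans]
            assert np.all(np.abs(fit.coefficients) < 3.5 * fit.bse.to_numpy())

    def test_no_f_terms_reduces_to_left_truncated_fit(self, exp_decay_cohort):
        tab, _ = exp_decay_cohort
        res = fit_separate(tab, f_terms=())
        f23 = res.fits["23"]
        assert f23.names == ["z_cont", "z_bin"]
        layout = ic.to_separate_layout(tab, "23", clock="forward")
        direct = ic.fit_cox(layout, ["z_cont", "z_bin"])
        assert f23.log_pl == pytest.approx(direct.log_pl, abs=1e-9)

    def test_too_few_events_refused(self):
        df = pd.DataFrame(
            {
                "id": range(8), "entry": 0.0,
                "d": [1.0, 1.5, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan],
                "dd_time": np.nan,
                "time": [2.0, 3.0, 1.0, 2.0, 3.0, 4.0, 2.5, 3.5],
                "status": [1, 1, 1, 1, 0, 0, 1, 0],
                "z": [0.1, -0.2, 0.3, 0.0, 1.0, -1.0, 0.5, 0.2],
            }
        )
        with pytest.raises(CoxError, match="too few 2->3 events"):
            fit_separate(ic.SubjectTable(df), f_terms=())


class TestSmoothHazard:
    def test_linear_cumulative_recovers_constant_slope(self):
        t = np.linspace(0.1, 10.0, 50)
        base = BaselineHazard(event_times=t, increments=np.full(50, 0.05))
        # cumulative = 0.05 * rank; make it exactly 0.5 * t instead
        base = BaselineHazard(
            event_times=t, increments=np.diff(np.concatenate([[0], 0.5 * t]))
        )
        sm = smooth_hazard(base)
        assert np.all(sm.hazard > 0.45) and np.all(sm.hazard < 0.55)

    def test_exponential_cohort_derivative_accuracy(self):
        rng = np.random.default_rng(3)
        n = 2000
        t = rng.exponential(1 / 0.7, n)
        cens = np.full(n, 3.0)
        df = pd.DataFrame(
            {"id": range(n), "transition": "13", "start": 0.0,
             "stop": np.minimum(t, cens), "status": (t <= cens).astype(int)}
        )
        fit = ic.fit_cox(df, [])
        base = ic.breslow_baseline(fit, df)
        sm = smooth_hazard(base)
        mae = np.mean(np.abs(sm.hazard - 0.7)) / 0.7
        assert mae < 0.15

    def test_decreasing_cumulative_clamped_with_warning(self):
        t = np.linspace(0.1, 5.0, 30)
        y = 0.3 * t
        y[12:18] -= np.linspace(0.0, 0.8, 6)  # injected dip
        incs = np.diff(np.concatenate([[0], y]))
        base = BaselineHazard.__new__(BaselineHazard)
        base.event_times = t
        base.increments = incs
        base.cumulative = y
        with pytest.warns(RuntimeWarning, match="clamped"):
            sm = smooth_hazard(base, lam=0.01)
        assert np.all(sm.hazard > 0)

    def test_too_few_event_times_rejected(self):
        base = BaselineHazard(event_times=[1.0, 2.0], increments=[0.1, 0.1])
        with pytest.raises(ValueError, match="at least 10"):
            smooth_hazard(base)


class TestSurfaces:
    def test_null_data_surface_near_one_both_approaches(self, null_cohort):
        tab, _ = null_cohort
        d_grid = np.arange(0.5, 3.01, 0.5)
        s_grid = np.arange(0.2, 2.01, 0.2)
        cJ = fit_joint(tab, relation="J.II").c_surface(d_grid, s_grid)
        assert np.all(np.abs(np.log(cJ.values)) < 0.5)
        resS = fit_separate(tab, f_terms=())
        surf = resS.hazard_ratio_surface(d_grid, s_grid)
        vals = surf.values[np.isfinite(surf.values)]
        assert len(vals) > 0.5 * surf.values.size
        assert np.abs(np.log(vals)).mean() < 0.5

    def test_masked_outside_baseline_support(self, null_cohort):
        tab, _ = null_cohort
        resS = fit_separate(tab, f_terms=())
        surf = resS.hazard_ratio_surface(
            d_grid=np.array([4.5]), s_grid=np.array([4.5])
        )
        assert np.isnan(surf.values).all()  # t = 9 beyond the observed support

    def test_reset_clock_surface_refused(self, exp_decay_cohort):
        tab, _ = exp_decay_cohort
        res = fit_separate(tab, clock="reset", f_terms=())
        with pytest.raises(ValueError, match="forward clock"):
            res.hazard_ratio_surface()

    def test_long_format_export(self, exp_decay_cohort):
        tab, _ = exp_decay_cohort
        surf = fit_joint(tab, relation="J.III.2").c_surface(
            d_grid=[1.0, 2.0], s_grid=[0.5, 1.0, 1.5]
        )
        frame = surf.to_frame()
        assert list(frame.columns) == ["d", "s", "value"]
        assert len(frame) == 6


class TestCompareModels:
    def test_aic_table_sorted_with_delta(self, exp_decay_cohort):
        tab, _ = exp_decay_cohort
        fits = [
            fit_joint(tab, relation=r)
            for r in ("J.I", "J.II", "J.III.1", "J.III.2", "J.IV")
        ]
        table = compare_models(fits)
        assert table["aic"].is_monotonic_increasing
        assert table["delta_aic"].iloc[0] == 0.0
        # data generated under the J.IV mechanism: a time-dependent relation
        # wins and ignoring the intermediate event is clearly worst
        assert table.iloc[0]["relation"] != "J.I"
        assert table.iloc[-1]["relation"] == "J.I"
        assert table["delta_aic"].iloc[-1] > 20

    def test_single_fit_trivial_table(self, exp_decay_cohort):
        tab, _ = exp_decay_cohort
        table = compare_models([fit_joint(tab, relation="J.II")])
        assert len(table) == 1 and table["delta_aic"].iloc[0] == 0.0

    def test_mixed_endpoints_refused(self, exp_decay_cohort):
        tab, _ = exp_decay_cohort
        a = fit_joint(tab, relation="J.II", endpoint="overall_survival")
        b = fit_joint(tab, relation="J.II", endpoint="distant_disease_free")
        with pytest.raises(ValueError, match="endpoints"):
            compare_models([a, b])

    def test_separate_fits_refused(self, exp_decay_cohort):
        tab, _ = exp_decay_cohort
        s = fit_separate(tab, f_terms=())
        with pytest.raises(ValueError, match="approach J"):
            compare_models([s])
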