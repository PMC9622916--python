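import numpy as np
import pandas as pd
import pytest

from bpgrs.simulate import GompertzHazard, SimConfig, simulate_cohort
from bpgrs.survival import (
    ConvergenceError,
    ExposureSpec,
    cox_loglik,
    event_indicator,
    fit_cox,
    fit_cox_arrays,
    ph_check,
    results_table,
    schoenfeld_residuals,
    trend_test,
)
from conftest import brute_force_efron_loglik


class TestPartialLikelihoodEngine:
    def test_toy_left_truncated_matches_brute_force(self, toy_truncated):
        for beta in ([0.0], [0.37], [-0.8], [1.5]):
            ll, _, _ = cox_loglik(np.array(beta), **{
                "X": toy_truncated["X"],
                "entry": toy_truncated["entry"],
                "exit_": toy_truncated["exit_"],
                "event": toy_truncated["event"],
            })
            brute = brute_force_efron_loglik(
                np.array(beta),
                toy_truncated["X"],
                toy_truncated["entry"],
                toy_truncated["exit_"],
                toy_truncated["event"],
            )
            assert ll == pytest.approx(brute, abs=1e-10)

    def test_gradient_matches_finite_differences(self, toy_truncated):
        beta = np.array([0.3])
        eps = 1e-6
        _, grad, hess = cox_loglik(beta, toy_truncated["X"], toy_truncated["entry"],
                                   toy_truncated["exit_"], toy_truncated["event"])
        llp, _, _ = cox_loglik(beta + eps, toy_truncated["X"], toy_truncated["entry"],
                               toy_truncated["exit_"], toy_truncated["event"])
        llm, _, _ = cox_loglik(beta - eps, toy_truncated["X"], toy_truncated["entry"],
                               toy_truncated["exit_"], toy_truncated["event"])
        assert grad[0] == pytest.approx((llp - llm) / (2 * eps), abs=1e-5)
        gp = cox_loglik(beta + eps, toy_truncated["X"], toy_truncated["entry"],
                        toy_truncated["exit_"], toy_truncated["event"])[1]
        gm = cox_loglik(beta - eps, toy_truncated["X"], toy_truncated["entry"],
                        toy_truncated["exit_"], toy_truncated["event"])[1]
        assert hess[0, 0] == pytest.approx((gp[0] - gm[0]) / (2 * eps), abs=1e-4)

    def test_agrees_with_lifelines_under_delayed_entry(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(1)
        n = 2500
        entry = rng.uniform(45, 73, n)
        X = np.column_stack([rng.integers(0, 2, n), rng.normal(size=n)]).astype(float)
        dur = rng.exponential(1 / (0.03 * np.exp(X @ [0.5, 0.3])), n)
        exit_ = entry + np.minimum(dur, 27)
        event = (dur < 27).astype(int)
        ours = fit_cox_arrays(X, entry, exit_, event, terms=["x1", "x2"])
        df = pd.DataFrame({"entry": entry, "exit": exit_, "event": event,
                           "x1": X[:, 0], "x2": X[:, 1]})
        cph = lifelines.CoxPHFitter()
        cph.fit(df, duration_col="exit", event_col="event", entry_col="entry")
        np.testing.assert_allclose(ours.coef, cph.params_.values, atol=5e-5)
        np.testing.assert_allclose(ours.se, cph.standard_errors_.values, rtol=1e-4)
        assert ours.loglik == pytest.approx(cph.log_likelihood_, abs=1e-6)

    def test_symmetric_groups_give_zero_coefficient(self):
        # two exposure groups with identical event histories
        entry = np.array([50.0, 50.0, 50.0, 50.0])
        exit_ = np.array([60.0, 70.0, 60.0, 70.0])
        event = np.array([1, 0, 1, 0])
        X = np.array([[0.0], [0.0], [1.0], [1.0]])
        fit = fit_cox_arrays(X, entry, exit_, event)
        assert fit.coef[0] == pytest.approx(0.0, abs=1e-9)

    def test_no_events_and_separation_raise(self):
        entry = np.zeros(4)
        exit_ = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.array([[0.0], [0.0], [1.0], [1.0]])
        with pytest.raises(ValueError, match="no events"):
            fit_cox_arrays(X, entry, exit_, np.zeros(4, dtype=int))
        # exposed always fail first -> monotone likelihood
        X = np.array([[1.0], [1.0], [1.0], [0.0], [0.0], [0.0]])
        exit_ = np.array([1.0, 2.0, 3.0, 11.0, 12.0, 13.0])
        event = np.array([1, 1, 1, 1, 1, 1])
        with pytest.raises(ConvergenceError):
            fit_cox_arrays(X, np.zeros(6), exit_, event)

    def test_exit_before_entry_rejected(self):
        with pytest.raises(ValueError, match="exceed the entry"):
            fit_cox_arrays(np.zeros((2, 1)), np.array([5.0, 5.0]),
                           np.array([4.0, 6.0]), np.array([1, 1]))

    def test_efron_handles_heavy_ties_like_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(4)
        n = 400
        entry = np.zeros(n)
        X = rng.normal(size=(n, 2))
        exit_ = 1.0 + rng.integers(0, 8, n).astype(float)  # many tied event times
        event = rng.integers(0, 2, n)
        event[:2] = 1
        ours = fit_cox_arrays(X, entry, exit_, event, terms=["a", "b"])
        df = pd.DataFrame({"T": exit_, "E": event, "a": X[:, 0], "b": X[:, 1]})
        cph = lifelines.CoxPHFitter()
        cph.fit(df, duration_col="T", event_col="E")
        np.testing.assert_allclose(ours.coef, cph.params_.values, atol=1e-5)
        assert ours.loglik == pytest.approx(cph.log_likelihood_, abs=1e-5)


class TestCohortModels:
    def test_per_sd_recovery_of_injected_effect(self):
        cfg = SimConfig(
            n=50_000,
            seed=21,
            hazards={"uc_aggressive": GompertzHazard(2e-3, 0.0), "death": GompertzHazard(5e-3, 0.05)},
            log_hr={"uc_aggressive": {"sbp_z": 0.25}},
        )
        cohort, _ = simulate_cohort(cfg)
        fit = fit_cox(cohort, ExposureSpec("sbp", "per_sd"), "uc_aggressive", adjustment=())
        assert abs(fit.coef[0] - 0.25) < 3 * fit.se[0]

    def test_cause_specific_event_split(self, default_cohort):
        cohort, _ = default_cohort
        total = event_indicator(cohort, "uc_total").sum()
        parts = (
            event_indicator(cohort, "uc_nonaggressive").sum()
            + event_indicator(cohort, "uc_aggressive").sum()
        )
        assert total == parts

    def test_nested_model_likelihood_monotone(self, default_cohort):
        cohort, _ = default_cohort
        small = fit_cox(cohort, ExposureSpec("sbp", "per_sd"), "uc_total", adjustment=())
        big = fit_cox(cohort, ExposureSpec("sbp", "per_sd"), "uc_total",
                      adjustment=("smoking",))
        assert big.loglik >= small.loglik - 1e-9

    def test_trend_test_requires_3_categories_and_detects_trend(self, default_cohort):
        cohort, _ = default_cohort
        z, p = trend_test(cohort, ExposureSpec("wgrs", "categorical"), "uc_total",
                          adjustment=())
        assert 0 <= p <= 1
        with pytest.raises(ValueError, match="categorical"):
            trend_test(cohort, ExposureSpec("sbp", "per_sd"), "uc_total")

    def test_wgrs_trend_positive_under_injected_effect(self):
        cfg = SimConfig(
            n=20_000,
            seed=31,
            hazards={"uc_nonaggressive": GompertzHazard(3e-3, 0.0), "death": GompertzHazard(5e-3, 0.05)},
            log_hr={"uc_nonaggressive": {"wgrs_z": 0.3}},
        )
        cohort, _ = simulate_cohort(cfg)
        z, p = trend_test(cohort, ExposureSpec("wgrs", "categorical"),
                          "uc_nonaggressive", adjustment=())
        assert z > 0 and p < 1e-4

    def test_results_table_layout(self, default_cohort):
        cohort, _ = default_cohort
        tab = results_table(cohort, ["uc_total"], [ExposureSpec("sbp", "categorical")],
                            adjustment=())
        assert set(tab["term"]) == {"sbp_cat1", "sbp_cat2", "sbp_cat3", "sbp_cat4", "sbp_per_sd"}
        ref = tab.loc[tab["term"] == "sbp_cat1", "hr"].iloc[0]
        assert ref == 1.0


class TestProportionalHazardsCheck:
    def test_residuals_sum_to_zero_at_mle(self, default_cohort):
        cohort, _ = default_cohort
        fit = fit_cox(cohort, ExposureSpec("sbp", "per_sd"), "uc_total", adjustment=())
        resid, _ = schoenfeld_residuals(fit)
        assert np.abs(resid.sum(axis=0)).max() < 1e-6

    def test_matches_r_cox_zph(self, tmp_path):
        """Independent oracle: the survival package's cox.zph on the same data."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        rng = np.random.default_rng(5)
        n = 1500
        entry = rng.uniform(45, 73, n)
        X = np.column_stack([rng.normal(size=n), rng.integers(0, 2, n)]).astype(float)
        dur = rng.exponential(1 / (0.02 * np.exp(X @ [0.3, 0.4])), n)
        exit_ = entry + np.minimum(dur, 25)
        event = (dur < 25).astype(int)
        fit = fit_cox_arrays(X, entry, exit_, event, terms=["x1", "x2"])
        ours = ph_check(fit, transform="identity")
        csv = tmp_path / "d.csv"
        pd.DataFrame({"entry": entry, "exit": exit_, "event": event,
                      "x1": X[:, 0], "x2": X[:, 1]}).to_csv(csv, index=False)
        script = (
            'library(survival); d <- read.csv("%s"); '
            "f <- coxph(Surv(entry, exit, event) ~ x1 + x2, data=d); "
            'z <- cox.zph(f, transform="identity"); '
            'write.csv(z$table, "%s")' % (csv, tmp_path / "zph.csv")
        )
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        r_tab = pd.read_csv(tmp_path / "zph.csv", index_col=0)
        # same diagnostic family, slightly different residual scaling: close, not exact
        assert ours.loc["GLOBAL", "chi2"] == pytest.approx(r_tab.loc["GLOBAL", "chisq"], rel=0.05)
        for term in ("x1", "x2"):
            assert ours.loc[term, "chi2"] == pytest.approx(r_tab.loc[term, "chisq"], rel=0.25, abs=0.3)

    def test_calibrated_under_proportional_hazards(self):
        rej = 0
        R = 120
        for seed in range(R):
            rng = np.random.default_rng(40_000 + seed)
            n = 600
            entry = rng.uniform(45, 73, n)
            X = rng.normal(size=(n, 1))
            dur = rng.exponential(1 / (0.03 * np.exp(0.3 * X[:, 0])), n)
            exit_ = entry + np.minimum(dur, 25)
            event = (dur < 25).astype(int)
            fit = fit_cox_arrays(X, entry, exit_, event)
            rej += ph_check(fit).loc["GLOBAL", "p"] < 0.05
        assert abs(rej / R - 0.05) < 0.06  # 3 binomial SE at R=120

    def test_detects_time_varying_effect(self):
        hits = 0
        R = 25
        for seed in range(R):
            rng = np.random.default_rng(50_000 + seed)
            n = 5000
            entry = rng.uniform(45, 60, n)
            x = rng.integers(0, 2, n).astype(float)
            # effect reverses at age 62: strong PH violation, simulated by
            # two-segment inversion of the piecewise-constant hazard
            h1 = 0.05 * np.exp(0.8 * x)
            h2 = 0.05 * np.exp(-0.8 * x)
            e_draw = rng.exponential(size=n)
            cum1 = h1 * np.clip(62.0 - entry, 0.0, None)
            t = np.where(
                e_draw < cum1,
                entry + e_draw / h1,
                np.maximum(entry, 62.0) + (e_draw - cum1) / h2,
            )
            admin = entry + 25
            event = (t < admin).astype(int)
            exit_ = np.minimum(t, admin)
            fit = fit_cox_arrays(x[:, None], entry, exit_, event)
            hits += ph_check(fit).loc["x0", "p"] < 0.05
        assert hits / R >= 0.8

    def test_too_few_events_rejected(self):
        entry = np.array([50.0, 50.0, 51.0])
        exit_ = np.array([55.0, 60.0, 61.0])
        event = np.array([1, 0, 0])
        fit = fit_cox_arrays(np.array([[0.5], [0.0], [1.0]]), entry, exit_, event)
        with pytest.raises(ValueError, match="at least 2"):
            ph_check(fit)
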