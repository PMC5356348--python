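import numpy as np
import pandas as pd
import pytest
from scipy.optimize import curve_fit

from reachdecomp.fitting import (FitConfig, FitError, compute_rmse,
                                 empirical_bayes, fit_nlme,
                                 initialize_two_stage)
from reachdecomp.model import PopulationParams, SubjectParams
from reachdecomp.synthetic import generate_cohort, stroke_config


def independent_nls(trials_one_subject):
    """Oracle: direct scipy curve_fit of the structural model, natural scale."""
    sub = trials_one_subject
    t = sub["t"].to_numpy(float)
    k = sub["target"].to_numpy(int)
    y = sub["mt_ms"].to_numpy(float)

    def f(X, A, tau, C, d1, d2, d3, d4, d5):
        tt, kk = X
        D = np.array([d1, d2, d3, d4, d5])
        return A * np.exp(-tt / tau) + C * tt + D[kk.astype(int) - 1]

    p0 = [200.0, 40.0, 0.5, 400, 400, 400, 400, 400]
    popt, _ = curve_fit(f, (t, k), y, p0=p0, maxfev=20000)
    return popt


class TestOracleEquivalence:
    def test_saem_matches_nls_in_the_noise_free_limit(self, noise_free_cohort):
        """Zero noise, zero dispersion: fixed effects within 0.1% of NLS."""
        trials = noise_free_cohort.trials
        res = fit_nlme(trials, FitConfig(seed=0))
        oracle = independent_nls(trials[trials.subject == "S1"])
        for est, ref in zip(res.population.fixed, oracle):
            assert est == pytest.approx(ref, rel=1e-3)

    def test_noise_free_eb_matches_nls_under_diffuse_prior(self, noise_free_cohort):
        trials = noise_free_cohort.trials[noise_free_cohort.trials.subject == "S1"]
        oracle = independent_nls(trials)
        pop = PopulationParams((250.0, 50.0, 1.0, 400, 400, 400, 400, 400),
                               (4.0, 4.0, 100.0, 1e6, 1e6, 1e6, 1e6, 1e6),
                               1.0)
        sp = empirical_bayes(trials, pop)[0]
        for est, ref in zip(sp.as_vector(), oracle):
            assert est == pytest.approx(ref, rel=5e-3)


class TestInitialization:
    def test_noise_free_initialization_recovers_truth(self, noise_free_cohort):
        init = initialize_two_stage(noise_free_cohort.trials)
        sp = noise_free_cohort.subjects[0]
        assert init.population.fixed[0] == pytest.approx(sp.A, rel=1e-4)
        assert init.population.fixed[1] == pytest.approx(sp.tau, rel=1e-4)
        assert init.population.fixed[2] == pytest.approx(sp.C, abs=1e-3)

    def test_flat_learner_does_not_crash(self):
        """A ~ 0 subjects (no visible learning) must initialize finitely."""
        cfg = stroke_config(3, seed=21, a_median=1e-2, a_log_sd=0.0)
        co = generate_cohort(cfg)
        init = initialize_two_stage(co.trials)
        assert np.all(np.isfinite(init.phi))
        assert not init.excluded

    def test_initialization_invariant_to_subject_order(self, stroke_cohort):
        trials = stroke_cohort.trials
        shuffled = trials.sample(frac=1.0, random_state=1)
        a = initialize_two_stage(trials)
        b = initialize_two_stage(shuffled)
        # row order changes floating-point accumulation inside the solver,
        # so equality is to solver precision, not bitwise
        np.testing.assert_allclose(a.population.fixed, b.population.fixed,
                                   rtol=1e-5)


class TestRmse:
    def test_perfect_predictions_give_zero(self, noise_free_cohort):
        assert compute_rmse(noise_free_cohort.trials,
                            noise_free_cohort.subjects)["overall"] == \
            pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_residuals(self):
        sp = SubjectParams("s", 0.0, 1.0, 0.0, (100.0,) * 5)
        trials = pd.DataFrame({
            "subject": ["s", "s"], "group": ["g", "g"],
            "t": [1, 2], "target": [1, 1], "mt_ms": [103.0, 96.0]})
        # residuals {3, -4} -> sqrt(25/2)
        assert compute_rmse(trials, [sp])["overall"] == \
            pytest.approx(3.5355, abs=1e-4)

    def test_missing_subject_params_rejected(self, noise_free_cohort):
        with pytest.raises(ValueError):
            compute_rmse(noise_free_cohort.trials, [])

    def test_well_specified_fit_recovers_noise_floor(self, stroke_fit):
        """RMSE of a correct model ~ the generating residual SD (76 ms)."""
        assert stroke_fit.rmse["overall"] == pytest.approx(76.0, rel=0.10)


class TestEmpiricalBayes:
    def test_zero_variance_returns_population_means(self, stroke_cohort):
        pop = PopulationParams((279.0, 64.0, 1.11, 328, 354, 380, 406, 432),
                               (0.0,) * 8, 76.0)
        trials = stroke_cohort.trials[stroke_cohort.trials.subject == "S1"]
        sp = empirical_bayes(trials, pop)[0]
        np.testing.assert_allclose(sp.as_vector(), pop.mean_subject().as_vector(),
                                   rtol=1e-4)

    def test_uninformative_likelihood_returns_population_means(self, stroke_cohort):
        pop = PopulationParams((279.0, 64.0, 1.11, 328, 354, 380, 406, 432),
                               (0.1,) * 8, 1e7)
        trials = stroke_cohort.trials[stroke_cohort.trials.subject == "S2"]
        sp = empirical_bayes(trials, pop)[0]
        np.testing.assert_allclose(sp.as_vector(), pop.mean_subject().as_vector(),
                                   rtol=1e-3)


class TestPopulationFit:
    def test_determinism(self, stroke_cohort):
        cfg = FitConfig(seed=5, n_burn=40, n_iter=20)
        a = fit_nlme(stroke_cohort.trials, cfg)
        b = fit_nlme(stroke_cohort.trials, cfg)
        np.testing.assert_array_equal(a.phi, b.phi)
        pd.testing.assert_frame_equal(a.trace, b.trace)

    def test_zero_dispersion_cohort_shrinks_variances(self):
        cfg = stroke_config(6, seed=9, a_log_sd=0, tau_log_sd=0, c_sd=0,
                            d_sd=0, sigma_eps=76.0)
        res = fit_nlme(generate_cohort(cfg).trials, FitConfig(seed=9))
        mu = np.array(res.population.fixed)
        om2 = np.array(res.population.omega2)
        # log-scale components against 5% of 1, natural against fixed^2
        assert np.all(om2[:2] < 0.05)
        assert np.all(om2[2:] < 0.05 * np.maximum(mu[2:] ** 2, 1.0))

    def test_group_medians_recovered_at_stroke_operating_point(self):
        """Median EB estimates track the realized cohort medians."""
        errs = []
        for seed in (0, 1, 2):
            co = generate_cohort(stroke_config(16, seed=seed))
            res = fit_nlme(co.trials, FitConfig(seed=seed))
            fm = res.params_frame().median(numeric_only=True)
            tm = co.params_frame().median(numeric_only=True)
            errs.append(abs(fm["A"] - tm["A"]) / tm["A"])
        assert np.median(errs) < 0.20

    def test_eb_estimates_correlate_with_generating_params(self, stroke_cohort,
                                                           stroke_fit):
        fit = stroke_fit.params_frame().set_index("subject")
        true = stroke_cohort.params_frame().set_index("subject").loc[fit.index]
        assert np.corrcoef(np.log(fit["A"]), np.log(true["A"]))[0, 1] > 0.9
        assert np.corrcoef(np.log(fit["tau"]), np.log(true["tau"]))[0, 1] > 0.85
        assert np.corrcoef(fit["C"], true["C"])[0, 1] > 0.8

    def test_fatigue_term_improves_fit_on_fatigue_containing_data(self):
        co = generate_cohort(stroke_config(8, seed=3))
        full = fit_nlme(co.trials, FitConfig(seed=3))
        ablated = fit_nlme(co.trials, FitConfig(seed=3, drop_fatigue=True))
        assert full.rmse["overall"] < ablated.rmse["overall"]

    def test_target_intercepts_improve_fit(self):
        co = generate_cohort(stroke_config(8, seed=3))
        full = fit_nlme(co.trials, FitConfig(seed=3))
        ablated = fit_nlme(co.trials, FitConfig(seed=3, single_intercept=True))
        assert full.rmse["overall"] < ablated.rmse["overall"]

    def test_saem_does_not_degrade_the_initialization(self):
        """Approximate marginal log-likelihood: SAEM >= two-stage start."""
        for seed in (1, 2):
            cfg = stroke_config(6, seed=seed, trials_per_target=60)
            co = generate_cohort(cfg)
            res = fit_nlme(co.trials, FitConfig(seed=seed, compute_loglik=True))
            assert res.improved_over_init

    def test_single_subject_rejected(self, stroke_cohort):
        one = stroke_cohort.trials[stroke_cohort.trials.subject == "S1"]
        with pytest.raises(FitError):
            fit_nlme(one, FitConfig(seed=0))

    def test_non_finite_mt_named_in_error(self, stroke_cohort):
        trials = stroke_cohort.trials.copy()
        trials.loc[trials.index[5], "mt_ms"] = np.nan
        with pytest.raises(FitError, match="S1"):
            fit_nlme(trials, FitConfig(seed=0))


def test_config_validation():
    with pytest.raises(ValueError):
        FitConfig(n_burn=0)
    with pytest.raises(ValueError):
        FitConfig(step_exponent=0.4)
    with pytest.raises(ValueError):
        FitConfig(error_model="per_subject")
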