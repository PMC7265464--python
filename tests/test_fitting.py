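"""Simulation-based likelihoods, fitting machinery and model comparison."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from driftlearn import build_stimulus_set, make_model
from driftlearn.fitting import (
    DataSummaries,
    FitConfig,
    FitResult,
    choice_loglik,
    compare_models,
    fit_model,
    information_criteria,
    model_loglik,
    rt_loglik,
    summarize_conditions,
    total_loglik,
)


class TestSummaries:
    def test_two_trial_condition(self):
        df = pd.DataFrame(
            {"stim_id": [0, 0], "correct": [True, False],
             "t_r": [0.2, 0.4], "t_d": [0.1, 0.3]}
        )
        s = summarize_conditions(df)
        assert s.loc[0, "n"] == 2
        assert s.loc[0, "p_correct"] == 0.5
        assert s.loc[0, "rt_mean"] == pytest.approx(0.3)
        assert s.loc[0, "rt_var"] == pytest.approx(0.02)

    def test_all_correct_condition(self):
        df = pd.DataFrame(
            {"stim_id": [1] * 4, "correct": [True] * 4,
             "t_r": [0.2, 0.25, 0.3, 0.35], "t_d": [0.1] * 4}
        )
        assert summarize_conditions(df).loc[1, "p_correct"] == 1.0

    def test_matches_independent_groupby(self, ddm_cat_trials):
        s = summarize_conditions(ddm_cat_trials)
        for stim_id in ddm_cat_trials["stim_id"].unique():
            key = ("categorization", stim_id)
            sub = ddm_cat_trials[ddm_cat_trials.stim_id == stim_id]
            assert s.loc[key, "n"] == len(sub)
            assert s.loc[key, "p_correct"] == pytest.approx(sub["correct"].mean())
            assert s.loc[key, "rt_var"] == pytest.approx(np.var(sub["t_r"], ddof=1))


class TestLikelihoodTerms:
    def test_rt_peak_value(self):
        var, n = 0.04, 25
        ll = rt_loglik(0.3, 0.3, var, n)
        assert ll == pytest.approx(math.log(1 / math.sqrt(2 * math.pi * var / n)))

    def test_rt_matches_norm_logpdf(self):
        ll = rt_loglik(0.35, 0.30, 0.04, 25)
        assert ll == pytest.approx(norm.logpdf(0.35, 0.30, math.sqrt(0.04 / 25)),
                                   rel=1e-12)

    def test_rt_decreases_away_from_data(self):
        lls = [rt_loglik(0.3 + d, 0.3, 0.04, 25) for d in (0.0, 0.05, 0.1, 0.2)]
        assert all(a > b for a, b in zip(lls, lls[1:]))

    def test_choice_kernel_substitution(self):
        # P=1, n=10, model 0.9 -> 10 ln 0.9
        assert choice_loglik(0.9, 1.0, 10, 1e-9) == pytest.approx(10 * math.log(0.9))

    def test_choice_kernel_maximized_at_data(self):
        grid = np.linspace(0.05, 0.95, 50)
        lls = [choice_loglik(p, 0.7, 40, 1e-9) for p in grid]
        assert grid[int(np.argmax(lls))] == pytest.approx(0.7, abs=0.02)

    def test_choice_kernel_matches_per_trial_product(self):
        # brute-force oracle: product of per-trial Bernoulli terms
        rng = np.random.default_rng(0)
        outcomes = rng.random(50) < 0.8
        p_model = 0.73
        brute = np.sum(np.where(outcomes, math.log(p_model), math.log(1 - p_model)))
        assert choice_loglik(p_model, outcomes.mean(), 50, 1e-12) == pytest.approx(brute)

    def test_choice_extremes_clipped(self):
        assert np.isfinite(choice_loglik(0.0, 0.5, 10, 1e-4))
        assert np.isfinite(choice_loglik(1.0, 0.5, 10, 1e-4))


@pytest.fixture(scope="module")
def cat_fit_setup(cat_set):
    spec = make_model("ddm")
    data = spec.simulate(spec.defaults, cat_set, 20000, 909)
    return spec, DataSummaries.from_trials(data), cat_set


class TestTotalLoglik:
    def test_duplicated_trials_double_choice_term(self):
        df = pd.DataFrame(
            {"stim_id": [0] * 6 + [1] * 6,
             "correct": [True, True, False] * 4,
             "t_r": list(np.linspace(0.2, 0.4, 6)) * 2,
             "t_d": [0.1] * 12,
             "session": 0, "choice": 1, "difficulty": 1}
        )
        doubled = pd.concat([df, df], ignore_index=True)
        m = DataSummaries.from_trials(df)  # model == data, rt term = peak

        def rt_part(data_summary):
            total = 0.0
            for key, row in data_summary.marginal.iterrows():
                mr = m.marginal.loc[key]
                extra = ((0.1 * mr["td_mean"]) ** 2
                         + row["rt_var"] * row["n"] / mr["n"])
                total += rt_loglik(mr["rt_mean"], row["rt_mean"], row["rt_var"],
                                   row["n"], extra_var=extra)
            return total

        ds, dd = DataSummaries.from_trials(df), DataSummaries.from_trials(doubled)
        choice_single = total_loglik(m, ds, n_sim=1000) - rt_part(ds)
        choice_double = total_loglik(m, dd, n_sim=1000) - rt_part(dd)
        assert choice_double == pytest.approx(2 * choice_single, rel=1e-9)

    def test_generating_parameters_beat_mismatched(self, cat_fit_setup):
        spec, data, cat_set = cat_fit_setup
        cfg = FitConfig(n_sim=20000, sim_seed=5)
        ll_true = model_loglik(spec, {}, data, cat_set, cfg)
        for bad in ({"k": 7.0}, {"k": 14.0}, {"theta0": 0.3}, {"theta0": 1.0},
                    {"beta": 0.25}, {"beta": 0.6}, {"t_nd": 0.1}, {"t_nd": 0.45}):
            assert ll_true > model_loglik(spec, bad, data, cat_set, cfg)

    def test_finite_for_extreme_parameters(self, cat_fit_setup):
        spec, data, cat_set = cat_fit_setup
        cfg = FitConfig(n_sim=2000, sim_seed=5)
        ll = model_loglik(spec, {"k": 0.5, "theta0": 0.05}, data, cat_set, cfg)
        assert np.isfinite(ll)

    def test_frozen_seed_objective_deterministic(self, cat_fit_setup):
        spec, data, cat_set = cat_fit_setup
        cfg = FitConfig(n_sim=5000, sim_seed=5)
        a = model_loglik(spec, {"k": 9.0}, data, cat_set, cfg)
        b = model_loglik(spec, {"k": 9.0}, data, cat_set, cfg)
        assert a == b

    def test_frozen_seed_surface_smoother_than_fresh(self, cat_fit_setup):
        # common random numbers: the quadratic-detrended wiggle of a CRN
        # parameter sweep is much smaller than with per-evaluation reseeding
        spec, data, cat_set = cat_fit_setup
        ks = np.linspace(9.0, 11.0, 9)

        def sweep(seeds):
            return np.array([
                model_loglik(spec, {"k": k}, data, cat_set,
                             FitConfig(n_sim=5000, sim_seed=s))
                for k, s in zip(ks, seeds)
            ])

        def wiggle(lls):
            resid = lls - np.polyval(np.polyfit(ks, lls, 2), ks)
            return np.abs(np.diff(resid)).max()

        crn = sweep([5] * len(ks))
        fresh = sweep(range(100, 100 + len(ks)))
        assert wiggle(crn) < 0.6 * wiggle(fresh)


class TestInformationCriteria:
    def test_bic_substitution(self):
        # lnL = 0, q = 6, n = e -> BIC = 6
        assert information_criteria(0.0, 6, round(math.e))["bic"] == pytest.approx(
            6 * math.log(round(math.e)))
        assert information_criteria(0.0, 6, 3)["bic"] == pytest.approx(6 * math.log(3))

    def test_equal_likelihood_fewer_params_wins(self):
        small = information_criteria(-100.0, 4, 1000)
        big = information_criteria(-100.0, 8, 1000)
        assert small["bic"] < big["bic"]

    def test_log10_marginal_conversion(self):
        crit = information_criteria(-50.0, 3, 500)
        assert crit["log10_marginal"] == pytest.approx(-0.5 * crit["bic"] / math.log(10))


class TestCompareModels:
    def _result(self, name, loglik, q, n=1000):
        crit = information_criteria(loglik, q, n)
        return FitResult(model=name, params={}, free_names=[], loglik=loglik,
                         n_params=q, n_trials=n, n_evaluations=1, converged=True,
                         config=FitConfig(), **crit)

    def test_ranking_and_bayes_factor(self):
        table = compare_models([
            self._result("a", -100.0, 3),
            self._result("b", -140.0, 3),
        ])
        assert table["model"].tolist() == ["a", "b"]
        expected_bf = (-0.5 * (information_criteria(-140, 3, 1000)["bic"]
                               - information_criteria(-100, 3, 1000)["bic"])
                       / math.log(10))
        assert table["log10_bf_vs_best"].iloc[1] == pytest.approx(-expected_bf)
        assert bool(table["decisive"].iloc[1])

    def test_mismatched_n_rejected(self):
        with pytest.raises(ValueError):
            compare_models([self._result("a", -10, 2, n=100),
                            self._result("b", -10, 2, n=200)])


class TestFitModel:
    def test_single_parameter_recovery(self, cat_fit_setup):
        spec, _, cat_set = cat_fit_setup
        data = spec.simulate(spec.defaults, cat_set, 20000, 909)
        cfg = FitConfig(n_sim=10000, sim_seed=77, n_starts=1, maxfev=40)
        res = fit_model(spec, data, ["theta0"], cat_set, cfg,
                        init={"theta0": 0.45})
        assert res.params["theta0"] == pytest.approx(0.6, rel=0.1)
        assert res.n_params == 1 and res.n_trials == 20000

    def test_fitted_point_not_worse_than_truth(self, cat_fit_setup):
        spec, data, cat_set = cat_fit_setup
        cfg = FitConfig(n_sim=10000, sim_seed=77, n_starts=1, maxfev=40)
        trials = spec.simulate(spec.defaults, cat_set, 20000, 909)
        res = fit_model(spec, trials, ["theta0"], cat_set, cfg,
                        init={"theta0": 0.5})
        ll_truth = model_loglik(spec, {}, data, cat_set, cfg)
        assert res.loglik >= ll_truth - 2.0

    def test_deterministic_given_seeds(self, cat_fit_setup):
        spec, _, cat_set = cat_fit_setup
        data = spec.simulate(spec.defaults, cat_set, 5000, 909)
        cfg = FitConfig(n_sim=3000, sim_seed=77, n_starts=2, maxfev=15)
        r1 = fit_model(spec, data, ["k"], cat_set, cfg)
        r2 = fit_model(spec, data, ["k"], cat_set, cfg)
        assert r1.params["k"] == r2.params["k"]
        assert r1.loglik == r2.loglik

    def test_result_serializes(self, cat_fit_setup):
        spec, _, cat_set = cat_fit_setup
        data = spec.simulate(spec.defaults, cat_set, 2000, 1)
        cfg = FitConfig(n_sim=2000, sim_seed=3, n_starts=1, maxfev=5)
        d = fit_model(spec, data, ["k"], cat_set, cfg).to_dict()
        assert {"model", "params", "loglik", "bic", "n_sim"} <= set(d)
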