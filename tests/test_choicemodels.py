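"""Utility models, fits, marginal likelihoods and auxiliary regressions."""

import numpy as np
import pytest

import alloctrace as at
from alloctrace import choicemodels as cm
from alloctrace.allocations import Allocation, ChoiceProblem


A123 = Allocation((100, 200, 300))


@pytest.mark.parametrize(
    "alpha,expected", [(1.0, 100.0), (0.0, 600.0), (0.5, 350.0)]
)
def test_quasi_maximin_utility(alpha, expected):
    assert cm.utility_quasi_maximin(A123, alpha) == pytest.approx(expected)


def test_quasi_maximin_rejects_alpha_outside_unit_interval():
    with pytest.raises(ValueError):
        cm.utility_quasi_maximin(A123, 1.2)


@pytest.mark.parametrize(
    "beta,payoffs,expected",
    [
        (0.0, (100, 200, 300), 200.0),
        (1.0, (100, 200, 300), 200.0 - 20000.0 / 3.0),
        (7.3, (500, 500, 500), 500.0),
    ],
)
def test_mean_variance_utility(beta, payoffs, expected):
    assert cm.utility_mean_variance(Allocation(payoffs), beta) == pytest.approx(expected)


def test_choice_probability_invariant_to_common_utility_shift(default_problems):
    """Adding a constant to both options' utilities leaves P(N) unchanged:
    the likelihood depends only on the utility difference."""
    from scipy.special import expit

    _, problems = default_problems
    trials, _ = at.simulate_choices(problems, at.SimulationConfig(n_participants=1),
                                    np.random.default_rng(0))
    data = cm.ChoiceData.build(trials, problems)
    du = cm._du(data, "A", 0.8)
    assert np.allclose(expit(du + 5.0 - 5.0), expit(du))
    # and the stored design encodes only differences
    assert data.c_a.shape == data.y.shape


class TestIndependentFit:
    def test_recovers_strong_maximin_agent(self, default_problems):
        _, problems = default_problems
        cfg = at.SimulationConfig(
            n_participants=1, alpha_mean=0.9, alpha_sd=0.0,
            tau_log_mean=np.log(20.0), tau_log_sd=0.0,
        )
        trials, _ = at.simulate_choices(problems, cfg, np.random.default_rng(4))
        fit = cm.fit_choice_model(trials, problems, "A", mode="independent")
        assert abs(fit.param_mean[0] - 0.9) < 0.1

    def test_all_n_chooser_concentrates_alpha_high(self, default_problems):
        _, problems = default_problems
        trials, _ = at.simulate_choices(
            problems,
            at.SimulationConfig(n_participants=1, alpha_mean=1.0, alpha_sd=0.0,
                                tau_log_mean=np.log(500.0), tau_log_sd=0.0),
            np.random.default_rng(0),
        )
        assert all(t.choice == "N" for t in trials)
        fit = cm.fit_choice_model(trials, problems, "A", mode="independent")
        assert fit.param_mean[0] > 0.7
        assert fit.param_interval[0, 0] > 0.6


class TestHierarchicalFit:
    @pytest.fixture(scope="class")
    def hier_fit(self, small_experiment):
        _, problems, _, trials, _, truth = small_experiment
        fit = cm.fit_choice_model(trials, problems, "A", mode="hierarchical",
                                  seed=1, mcmc=dict(warmup=1500, draws=800))
        return fit, truth

    def test_converged_with_rhat_below_threshold(self, hier_fit):
        fit, _ = hier_fit
        assert fit.converged
        assert all(v < 1.1 for v in fit.rhat.values())

    def test_recovers_participant_alphas(self, hier_fit):
        fit, truth = hier_fit
        true_alpha = np.array([truth["agents"]["participants"][p]["param"]
                               for p in fit.participants])
        assert np.abs(fit.param_mean - true_alpha).mean() < 0.12

    def test_alpha_beta_positively_correlated_across_participants(self, small_experiment):
        """Both indices capture inequality aversion, so the per-participant
        estimates from the two models should co-vary strongly."""
        _, problems, _, trials, _, _ = small_experiment
        fa = cm.fit_choice_model(trials, problems, "A", mode="independent")
        fb = cm.fit_choice_model(trials, problems, "B", mode="independent")
        r = np.corrcoef(fa.param_mean, fb.param_mean)[0, 1]
        assert r > 0.5


class TestMarginalLikelihood:
    def test_empty_data_logml_zero(self):
        d = cm.ChoiceData(*[np.array([])] * 7)
        assert cm.quadrature_oracle_logml(None, None, "A", data=d) == 0.0

    def test_indifferent_options_forced_coin_flip(self):
        # du identically zero for every parameter value: logml = n log(1/2)
        n = 6
        d = cm.ChoiceData(
            participants=np.array(["s"] * n), y=np.ones(n),
            c_a=np.zeros(n), m_a=np.zeros(n), c_b=np.zeros(n), v_b=np.zeros(n),
            rt=np.ones(n),
        )
        assert cm.quadrature_oracle_logml(None, None, "A", data=d) == pytest.approx(
            n * np.log(0.5), abs=1e-6
        )
        assert cm._fit_one_grid(d, "A")[4] == pytest.approx(n * np.log(0.5), abs=1e-6)

    def test_grid_matches_adaptive_quadrature(self, small_experiment):
        _, problems, _, trials, _, _ = small_experiment
        data = cm.ChoiceData.build(trials, problems)
        for model in ("A", "B"):
            for lab, d in list(data.split())[:2]:
                oracle = cm.quadrature_oracle_logml(None, None, model, data=d)
                grid = cm._fit_one_grid(d, model)[4]
                assert abs(oracle - grid) < 1e-3

    def test_bf_antisymmetry(self, small_experiment):
        _, problems, _, trials, _, _ = small_experiment
        comp = cm.compare_models(trials, problems)
        assert comp.bayes_factor_ab * np.exp(comp.logml_b - comp.logml_a) == pytest.approx(1.0)

    def test_hierarchical_bridge_favours_generating_model(self, small_experiment):
        """Bridge-sampling marginal likelihoods of the hierarchical fits
        still favour the quasi-maximin model that generated the data."""
        _, problems, _, trials, _, _ = small_experiment
        mcmc = dict(warmup=1000, draws=500)
        fa = cm.fit_choice_model(trials, problems, "A", mode="hierarchical",
                                 seed=3, mcmc=mcmc)
        fb = cm.fit_choice_model(trials, problems, "B", mode="hierarchical",
                                 seed=4, mcmc=mcmc)
        la, ea = cm.marginal_likelihood(fa, seed=5)
        lb, eb = cm.marginal_likelihood(fb, seed=6)
        assert np.isfinite(la) and np.isfinite(lb)
        assert ea < 1.0 and eb < 1.0
        assert la > lb

    def test_comparing_model_to_itself_gives_bf_one(self, small_experiment):
        _, problems, _, trials, _, _ = small_experiment
        data = cm.ChoiceData.build(trials, problems)
        f = cm._fit_independent(data, "A")
        comp = cm.ModelComparison(logml_a=f.logml, logml_b=f.logml, method="quadrature")
        assert comp.bayes_factor_ab == pytest.approx(1.0)


def test_prior_sensitivity_leaves_comparison_unchanged(small_experiment):
    """The Bayes-factor direction and the posterior beta barely move across
    a 4-fold range of informative-prior scales."""
    _, problems, _, trials, _, _ = small_experiment
    records = cm.prior_sensitivity(trials, problems)
    directions = [r["bayes_factor_AB"] > 1.0 for r in records]
    assert len(set(directions)) == 1
    betas = [r["beta_posterior_mean"] for r in records]
    assert max(betas) - min(betas) < 0.3


class TestChoiceRate:
    def test_balanced_choices_interval_covers_zero(self, default_problems):
        _, problems = default_problems
        rng = np.random.default_rng(9)
        trials, _ = at.simulate_choices(
            problems,
            at.SimulationConfig(n_participants=12, alpha_mean=0.5, alpha_sd=0.0,
                                tau_log_mean=-8.0, tau_log_sd=0.0),
            rng,
        )  # tau ~ 0: coin-flip choices
        res = cm.fit_choice_rate(trials, seed=0)
        assert res.interval[0] < 0.0 < res.interval[1]

    def test_strong_preference_interval_excludes_zero(self, default_problems):
        cfg, problems = default_problems
        trials, _ = at.simulate_choices(problems, cfg, np.random.default_rng(2))
        res = cm.fit_choice_rate(trials, seed=0)
        assert res.interval[0] > 0.0
        # posterior median should be near the empirical logit under shrinkage
        rate = res.extra["rate"]
        assert abs(res.coef_median - np.log(rate / (1 - rate))) < 0.5


class TestRtModel:
    def test_requires_both_choice_types(self, default_problems):
        _, problems = default_problems
        trials, _ = at.simulate_choices(
            problems,
            at.SimulationConfig(n_participants=2, alpha_mean=1.0, alpha_sd=0.0,
                                tau_log_mean=np.log(500.0), tau_log_sd=0.0),
            np.random.default_rng(0),
        )
        with pytest.raises(ValueError, match="both choice types"):
            cm.fit_rt_model(trials)

    def test_detects_injected_choice_type_effect(self):
        cfg = at.SimulationConfig(seed=8, rt_choice_effect_s=0.3)
        rng = np.random.default_rng(8)
        problems = at.generate_problems(cfg, rng)
        trials, _ = at.simulate_choices(problems, cfg, rng)
        res = cm.fit_rt_model(trials, seed=4)
        # +0.3 s on U choices means a negative N-choice coefficient
        assert res.interval[1] < 0.0
        assert abs(res.coef_median + 0.3) < 0.12
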