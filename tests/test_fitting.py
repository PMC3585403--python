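import numpy as np
import pytest

import vwmchange as v
from vwmchange.fitting import (
    ParameterGrid,
    bernoulli_loglik,
    default_grid,
    fit_model,
    ip_response_probability,
    predict_trial_probs,
    response_probability,
)


class TestParameterGrid:
    def test_default_grids_cover_tested_ranges(self):
        for model in v.MODELS:
            grid = default_grid(model)
            for name, values in grid.axes.items():
                lo, hi = v.PARAM_RANGES[model][name]
                assert values[0] == lo and values[-1] == hi

    def test_out_of_range_values_rejected(self):
        with pytest.raises(ValueError):
            ParameterGrid("EP", {"J_1": np.array([0.5, 10.0]),
                                 "alpha": np.array([-1.0]),
                                 "p_change": np.array([0.5])})

    def test_empty_axis_rejected(self):
        with pytest.raises(ValueError):
            ParameterGrid("EP", {"J_1": np.array([]),
                                 "alpha": np.array([-1.0]),
                                 "p_change": np.array([0.5])})

    def test_integer_capacity_enforced(self):
        with pytest.raises(ValueError):
            ParameterGrid("SR", {"J_1": np.array([10.0]),
                                 "K": np.array([2.5]),
                                 "p_change": np.array([0.5])})


class TestResponseProbability:
    def test_ip_closed_form(self):
        params = {"K": 3, "epsilon": 0.2, "g": 0.25}
        assert ip_response_probability(params, 6, 1) == pytest.approx(
            0.5 * 0.8 + 0.5 * 0.25
        )
        assert ip_response_probability(params, 6, 0) == pytest.approx(0.25)
        assert ip_response_probability(params, 2, 1) == pytest.approx(0.8)

    def test_noiseless_limit(self):
        trials = v.generate_experiment(300, p_change_true=1.0, seed=20)
        big = trials.iloc[int(np.argmax(np.abs(trials["delta"])))]
        p = response_probability(
            "EP", {"J_1": 1e6, "alpha": 0.0, "p_change": 0.5}, big,
            n_mc=10_000, seed=0,
        )
        assert p >= 0.99

    def test_tie_convention_gives_floor_probability(self):
        """With zero precision and a neutral prior, d = 1 resolves to 'no'."""
        trials = v.generate_experiment(10, p_change_true=0.0, seed=21)
        p = response_probability(
            "EP", {"J_1": 0.0, "alpha": 0.0, "p_change": 0.5},
            trials.iloc[0], n_mc=1000, seed=1,
        )
        assert p == pytest.approx(1.0 / 2000.0)

    def test_table_estimator_matches_direct_estimator(self):
        trials = v.generate_experiment(200, seed=22)
        params = v.REFERENCE_PARAMS["VP"]
        p_tab = predict_trial_probs("VP", params, trials, n_mc=4000, seed=2)
        rng = np.random.default_rng(3)
        for i in rng.choice(len(trials), 8, replace=False):
            p_dir = response_probability("VP", params, trials.iloc[int(i)],
                                         n_mc=20_000, seed=int(i))
            assert abs(p_dir - p_tab[i]) < 0.03

    def test_probabilities_respect_floor(self):
        trials = v.generate_experiment(200, seed=23)
        p = predict_trial_probs("SR", v.REFERENCE_PARAMS["SR"], trials,
                                n_mc=100, seed=4)
        assert np.all(p >= 1 / 200) and np.all(p <= 1 - 1 / 200)


class TestFitModel:
    def test_coin_flip_responses_recover_neutral_prior(self):
        trials = v.generate_experiment(900, seed=24)
        coin = np.random.default_rng(5).integers(0, 2, len(trials))
        fit = fit_model("EP", trials, coin, grid=default_grid("EP", coarse=True),
                        n_mc=300, seed=6)
        assert fit.params["p_change"] == pytest.approx(0.5, abs=0.05)
        assert fit.log_likelihood == pytest.approx(900 * np.log(0.5), rel=0.01)

    def test_fit_is_deterministic(self):
        trials = v.generate_experiment(300, seed=25)
        responses = v.simulate_observer("SR", v.REFERENCE_PARAMS["SR"], trials,
                                        seed=26)
        kw = dict(grid=default_grid("SR", coarse=True), n_mc=200, seed=7)
        f1 = fit_model("SR", trials, responses, **kw)
        f2 = fit_model("SR", trials, responses, **kw)
        assert f1.params == f2.params
        assert np.array_equal(f1.log_likelihood_table, f2.log_likelihood_table)

    def test_log_likelihood_is_nonpositive(self, vp_recovery_study):
        for rec in vp_recovery_study:
            for fit in rec["fits"].values():
                assert fit.log_likelihood <= 0
                assert fit.log_likelihood_table.max() == pytest.approx(
                    fit.grid_max_log_likelihood
                )

    def test_ep_parameter_recovery(self):
        """Refitting EP-generated data recovers the power-law exponent."""
        gen = v.REFERENCE_PARAMS["EP"]
        hits = 0
        for seed in range(5):
            trials = v.generate_experiment(1800, seed=500 + seed)
            responses = v.simulate_observer("EP", gen, trials, seed=600 + seed)
            fit = fit_model("EP", trials, responses,
                            grid=default_grid("EP", coarse=True),
                            n_mc=500, seed=seed)
            if abs(fit.params["alpha"] - gen["alpha"]) <= 0.3:
                hits += 1
        assert hits >= 4

    def test_mc_jitter_under_control(self):
        """Doubling the MC samples barely moves the maximum logL.

        Checked at the module's default n_mc = 1000; below that the
        small-sample bias of the clipped MC probabilities still decays.
        """
        trials = v.generate_experiment(1800, seed=27)
        responses = v.simulate_observer("EP", v.REFERENCE_PARAMS["EP"], trials,
                                        seed=28)
        grid = default_grid("EP", coarse=True)
        ll = {}
        for n_mc in (1000, 2000):
            fit = fit_model("EP", trials, responses, grid=grid, n_mc=n_mc,
                            seed=29, refine=False)
            ll[n_mc] = fit.grid_max_log_likelihood
        assert abs(ll[1000] - ll[2000]) < 2.0

    def test_misaligned_inputs_rejected(self):
        trials = v.generate_experiment(10, seed=30)
        with pytest.raises(ValueError):
            fit_model("EP", trials, np.zeros(5))


def test_bernoulli_loglik_matches_closed_form():
    r = np.array([1, 0, 1, 1])
    p = np.array([0.8, 0.3, 0.5, 0.9])
    expected = np.log(0.8) + np.log(0.7) + np.log(0.5) + np.log(0.9)
    assert bernoulli_loglik(r, p) == pytest.approx(expected)
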