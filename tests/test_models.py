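import numpy as np
import pytest
from helpers import oracle_decision_variable, random_decision_configs

import vwmchange as v
from vwmchange.models import (
    allocate_precision,
    decision_variable,
    ip_response,
    log_decision_variable,
    map_response,
    prob_matching_response,
    sa_chunk_allocation,
    validate_params,
)
from vwmchange.fitting import response_probability
from vwmchange.summary import summarize


class TestChunkAllocation:
    def test_four_chunks_three_items(self):
        counts = sa_chunk_allocation(4, 3, np.random.default_rng(0))
        assert sorted(counts) == [1, 1, 2]

    def test_more_items_than_chunks(self):
        counts = sa_chunk_allocation(3, 5, np.random.default_rng(1))
        assert sorted(counts) == [0, 0, 1, 1, 1]

    def test_equal_chunks_and_items(self):
        assert list(sa_chunk_allocation(4, 4, np.random.default_rng(2))) == [1] * 4

    def test_extra_chunk_position_is_random(self):
        rng = np.random.default_rng(3)
        winners = {int(np.argmax(sa_chunk_allocation(4, 3, rng))) for _ in range(200)}
        assert winners == {0, 1, 2}

    @pytest.mark.parametrize("K,N", [(0, 3), (3, 0), (2.5, 3), (-1, 4)])
    def test_invalid_inputs(self, K, N):
        with pytest.raises(ValueError):
            sa_chunk_allocation(K, N, np.random.default_rng(0))


class TestAllocatePrecision:
    def test_ep_power_law(self):
        st = allocate_precision(
            "EP", {"J_1": 20.0, "alpha": -1.0, "p_change": 0.5}, 4,
            np.random.default_rng(0),
        )
        assert np.allclose(st.J_x, 5.0)
        assert st.J_x is st.J_y

    def test_vp_gamma_mean(self):
        params = v.REFERENCE_PARAMS["VP"]
        rng = np.random.default_rng(1)
        draws = [allocate_precision("VP", params, 4, rng).J_x for _ in range(25_000)]
        mean = np.mean(np.concatenate(draws))
        expected = params["J1_bar"] * 4 ** params["alpha"]
        assert mean == pytest.approx(expected, rel=0.02)

    def test_vp_displays_independent(self):
        st = allocate_precision(
            "VP", v.REFERENCE_PARAMS["VP"], 6, np.random.default_rng(2)
        )
        assert not np.allclose(st.J_x, st.J_y)

    def test_sr_over_capacity(self):
        st = allocate_precision(
            "SR", {"J_1": 14.2, "K": 4, "p_change": 0.5}, 6, np.random.default_rng(3)
        )
        positive = st.J_x[st.J_x > 0]
        assert len(positive) == 4 and np.allclose(positive, 14.2 / 4)
        assert np.sum(st.J_x == 0) == 2

    def test_ip_memorized_subset(self):
        st = allocate_precision(
            "IP", {"K": 3, "epsilon": 0.1, "g": 0.2}, 6, np.random.default_rng(4)
        )
        assert len(st.memorized) == 3
        assert st.J_x is None

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            validate_params("EP", {"J_1": 20.0, "alpha": 0.5, "p_change": 0.5})
        with pytest.raises(ValueError):
            validate_params("VP", {"J1_bar": 50.0, "tau": -1.0, "alpha": -1.0,
                                   "p_change": 0.5})
        with pytest.raises(ValueError):
            validate_params("XX", {})


class TestDecisionVariable:
    def test_uninformative_measurements_leave_prior(self):
        x = np.array([0.2, -1.0, 2.0])
        y = np.array([1.2, 0.4, -2.5])
        z = np.zeros(3)
        assert decision_variable(x, y, z, z, 0.5) == pytest.approx(1.0)
        assert decision_variable(x, y, z, z, 0.7) == pytest.approx(0.7 / 0.3)

    def test_display_swap_symmetry(self):
        rng = np.random.default_rng(5)
        x, y = rng.uniform(-np.pi, np.pi, 4), rng.uniform(-np.pi, np.pi, 4)
        kx, ky = rng.gamma(2, 3, 4), rng.gamma(2, 3, 4)
        d1 = log_decision_variable(x, y, kx, ky, 0.4)
        d2 = log_decision_variable(y, x, ky, kx, 0.4)
        assert d1 == pytest.approx(d2, rel=1e-12)

    def test_matches_quadrature_oracle(self):
        rng = np.random.default_rng(6)
        for cfg in random_decision_configs(20, rng):
            d = decision_variable(**cfg)
            d_oracle = oracle_decision_variable(**cfg)
            assert d == pytest.approx(d_oracle, rel=1e-4)

    def test_zero_precision_items_are_transparent(self):
        # appending an unencoded item only changes the 1/N normalization
        x, y = np.array([0.3]), np.array([0.9])
        d1 = decision_variable(x, y, np.array([5.0]), np.array([5.0]), 0.5)
        d2 = decision_variable(
            np.array([0.3, 1.0]), np.array([0.9, -2.0]),
            np.array([5.0, 0.0]), np.array([5.0, 0.0]), 0.5,
        )
        assert d2 == pytest.approx((d1 + 1) / 2, rel=1e-10)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            log_decision_variable([0.1], [0.1, 0.2], [1.0], [1.0], 0.5)


class TestResponseRules:
    def test_map_rule(self):
        assert map_response(2.0) == 1
        assert map_response(0.5) == 0
        assert map_response(1.0) == 0  # tie resolves to "no change"

    def test_probability_matching_coin_limit(self):
        rng = np.random.default_rng(7)
        rate = np.mean([prob_matching_response(3.7, 0.0, rng) for _ in range(100_000)])
        assert rate == pytest.approx(0.5, abs=0.005)

    def test_probability_matching_symmetric_point(self):
        rng = np.random.default_rng(8)
        rate = np.mean([prob_matching_response(1.0, 1.0, rng) for _ in range(50_000)])
        assert rate == pytest.approx(0.5, abs=0.01)

    def test_probability_matching_map_limit(self):
        rng = np.random.default_rng(9)
        rate = np.mean([prob_matching_response(2.0, 1000.0, rng)
                        for _ in range(10_000)])
        assert rate > 0.999

    def test_negative_gain_rejected(self):
        with pytest.raises(ValueError):
            prob_matching_response(1.0, -1.0, np.random.default_rng(0))


class TestIPResponse:
    @staticmethod
    def _trial(n, change, loc):
        trials = v.generate_experiment(1, set_sizes=[n], p_change_true=change,
                                       seed=0)
        t = trials.iloc[0]
        return t

    def test_false_alarm_rate_is_g(self):
        params = {"K": 4, "epsilon": 0.1, "g": 0.25}
        t = self._trial(3, 0.0, -1)
        rng = np.random.default_rng(10)
        rate = np.mean([ip_response(t, params, rng) for _ in range(100_000)])
        assert rate == pytest.approx(0.25, abs=0.005)

    def test_partial_memorization_hit_rate(self):
        # N=6, K=3: change noticed w.p. 1/2 -> rate (1/2)(1-eps) + (1/2) g
        params = {"K": 3, "epsilon": 0.2, "g": 0.3}
        t = self._trial(6, 1.0, None)
        rng = np.random.default_rng(11)
        rate = np.mean([ip_response(t, params, rng) for _ in range(100_000)])
        assert rate == pytest.approx(0.5 * 0.8 + 0.5 * 0.3, abs=0.01)

    def test_perfect_observer(self):
        params = {"K": 8, "epsilon": 0.0, "g": 0.0}
        t = self._trial(4, 1.0, None)
        rng = np.random.default_rng(12)
        assert all(ip_response(t, params, rng) == 1 for _ in range(100))


class TestModelRelations:
    def test_vp_with_tiny_tau_reduces_to_ep(self):
        """As the precision-variability scale tau -> 0, VP -> EP.

        Each probability is a 10^4-sample Monte-Carlo estimate, so per-trial
        differences are bounded at 3.5 binomial sigma and the mean
        discrepancy across trials (where the MC noise averages out) must
        vanish.
        """
        trials = v.generate_experiment(20, seed=13)
        ep = {"J_1": 20.0, "alpha": -1.0, "p_change": 0.5}
        vp = {"J1_bar": 20.0, "tau": 1e-3, "alpha": -1.0, "p_change": 0.5}
        n_mc = 10_000
        diffs = []
        for i in range(10):
            t = trials.iloc[i]
            p_ep = response_probability("EP", ep, t, n_mc=n_mc, seed=100 + i)
            p_vp = response_probability("VP", vp, t, n_mc=n_mc, seed=200 + i)
            sigma = np.sqrt(2 * max(p_ep * (1 - p_ep), 0.05) / n_mc)
            assert abs(p_ep - p_vp) < 3.5 * sigma
            diffs.append(p_ep - p_vp)
        assert abs(np.mean(diffs)) < 0.005

    def test_sr_equals_ep_below_capacity(self):
        """SR with N <= K and alpha = -1 is the same allocation as EP."""
        trials = v.generate_experiment(500, set_sizes=[2, 4], seed=14)
        ep = {"J_1": 14.2, "alpha": -1.0, "p_change": 0.5}
        sr = {"J_1": 14.2, "K": 4, "p_change": 0.5}
        r_ep = v.simulate_observer("EP", ep, trials, seed=15)
        r_sr = v.simulate_observer("SR", sr, trials, seed=15)
        assert np.array_equal(r_ep, r_sr)

    @pytest.mark.parametrize("model", ["SA", "SR", "EP", "VP"])
    def test_psychometric_monotone_in_magnitude(self, model):
        """Report rate rises with change magnitude (one small inversion allowed)."""
        trials = v.generate_experiment(
            110_000, set_sizes=[4], p_change_true=1.0, seed=16
        )
        responses = v.simulate_observer(
            model, v.REFERENCE_PARAMS[model], trials, seed=17
        )
        stats = summarize(trials, responses)
        curve = stats.psychometric[4][1:]  # change bins only
        inversions = np.maximum(-np.diff(curve), 0.0)
        assert np.sum(inversions > 1e-12) <= 1
        assert np.all(inversions < 0.01)

    def test_ip_false_alarms_flat_in_set_size(self):
        """The IP signature: false alarms do not depend on set size."""
        trials = v.generate_experiment(40_000, seed=18)
        params = v.REFERENCE_PARAMS["IP"]
        responses = v.simulate_observer("IP", params, trials, seed=19)
        stats = summarize(trials, responses)
        for n in stats.set_sizes:
            m = stats.n_nochange[n]
            sigma = np.sqrt(params["g"] * (1 - params["g"]) / m)
            assert abs(stats.fa_rate[n] - params["g"]) < 4 * sigma
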