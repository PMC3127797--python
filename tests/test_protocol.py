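"""Two-session protocol: initialization, sessions, ensembles, reproducibility."""

import numpy as np
import pytest

import netscape as ns
from netscape.protocol import derive_seed, representative_state


class TestInitializeWeights:
    def test_deterministic(self, fan):
        a = ns.initialize_weights(fan, 77)
        b = ns.initialize_weights(fan, 77)
        np.testing.assert_array_equal(a.values, b.values)

    def test_support_and_mean(self, fan):
        draws = np.concatenate([ns.initialize_weights(fan, s, 1.0).values
                                for s in range(300)])
        assert draws.max() <= 1.0 and draws.min() >= -1.0
        # U(-1,1): sd = 1/sqrt(3)
        assert abs(draws.mean()) < 3 / np.sqrt(3 * draws.size)

    def test_bad_half_width(self, fan):
        with pytest.raises(ValueError):
            ns.initialize_weights(fan, 0, -1.0)


class TestSessionOne:
    def test_zero_error_start_returns_immediately(self, fan, D_o, fan_zero_fit):
        res = ns.run_session_one(fan, fan_zero_fit.final_params, D_o)
        assert res.E_o_star < 1e-12
        assert res.trace.n_iterations <= 1
        assert res.trace.stop_reason in ("plateau", "gradient_zero")

    def test_wrong_role_rejected(self, fan):
        pts = ns.generate_new_points(6, seed=0)
        with pytest.raises(ValueError):
            ns.run_session_one(fan, ns.initialize_weights(fan, 0), pts)

    def test_error_matches_sse_at_sampled_state(self, stacked, D_o):
        res = ns.run_session_one(stacked, ns.initialize_weights(stacked, 5), D_o)
        assert res.E_o_star == pytest.approx(
            ns.sse_error(stacked, res.sampled_params, D_o), rel=1e-12)


class TestSessionTwo:
    @pytest.fixture(scope="class")
    def setup(self, fan, D_o, exp_config):
        s1 = ns.run_session_one(fan, ns.initialize_weights(fan, 1), D_o)
        pool = ns.sample_buffer_pool(s1.f_o, exp_config.pool_size, seed=2)
        return s1, pool

    def test_zero_budget_keeps_f_o(self, fan, D_o, setup):
        s1, pool = setup
        cfg = ns.ExperimentConfig(limited_budget=0)  # T = 0: no training
        rec = ns.run_session_two(fan, s1.sampled_params, D_o, pool, 99, cfg)
        np.testing.assert_array_equal(rec.final_params, s1.sampled_params.values)
        assert rec.E_o == pytest.approx(s1.E_o_star, abs=1e-12)
        D_n = ns.generate_new_points(6, seed=rec.new_seed)
        assert rec.E_n == pytest.approx(ns.sse_error(fan, s1.sampled_params, D_n),
                                        rel=1e-12)

    def test_trial_seed_determinism(self, fan, D_o, setup, exp_config):
        s1, pool = setup
        a = ns.run_session_two(fan, s1.sampled_params, D_o, pool, 123, exp_config)
        b = ns.run_session_two(fan, s1.sampled_params, D_o, pool, 123, exp_config)
        assert a.E_o == b.E_o and a.E_n == b.E_n
        np.testing.assert_array_equal(a.f_n_grid, b.f_n_grid)

    def test_union_error_bounds_buffer_error(self, fan, D_o, setup, exp_config):
        s1, pool = setup
        rec = ns.run_session_two(fan, s1.sampled_params, D_o, pool, 7, exp_config)
        D_b = ns.draw_buffer_subset(pool, 6, seed=rec.buffer_seed)
        D_n = ns.generate_new_points(6, seed=rec.new_seed)
        union_x = np.r_[D_n.x, D_b.x]
        union_t = np.r_[D_n.t, D_b.t]
        e_union = ns.sse_error(fan, rec.final_params, (union_x, union_t))
        e_buffer = ns.sse_error(fan, rec.final_params, D_b)
        assert e_union >= e_buffer - 1e-15


class TestTrialEnsemble:
    def test_single_trial(self, fan, D_o, exp_config):
        s1 = ns.run_session_one(fan, ns.initialize_weights(fan, 1), D_o)
        recs = ns.run_trial_ensemble(fan, s1, D_o, exp_config, n_trials=1)
        assert len(recs) == 1

    def test_master_seed_reproducibility(self, fan, D_o, exp_config):
        s1 = ns.run_session_one(fan, ns.initialize_weights(fan, 1), D_o)
        a = ns.run_trial_ensemble(fan, s1, D_o, exp_config, n_trials=3)
        b = ns.run_trial_ensemble(fan, s1, D_o, exp_config, n_trials=3)
        np.testing.assert_array_equal([r.E_o for r in a], [r.E_o for r in b])
        np.testing.assert_array_equal([r.E_n for r in a], [r.E_n for r in b])

    def test_errors_within_theoretical_bound(self, trial_ensembles, exp_config):
        """Every recorded error is bounded by P times the squared output width."""
        for s1, recs in trial_ensembles.values():
            for r in recs:
                assert 0 <= r.E_o <= 6 * 1.0
                assert 0 <= r.E_n <= 6 * 1.0


class TestInitializationEnsemble:
    def test_single_init_consistency(self, fan, D_o, exp_config):
        ens = ns.run_initialization_ensemble(fan, D_o, 1, "unlimited",
                                             master_seed=555, config=exp_config)
        init = ns.initialize_weights(fan, derive_seed(555, 1, 0),
                                     exp_config.half_width)
        direct = ns.run_session_one(fan, init, D_o, exp_config.unlimited)
        assert ens.errors[0] == direct.E_o_star

    def test_invalid_arguments(self, fan, D_o):
        with pytest.raises(ValueError):
            ns.run_initialization_ensemble(fan, D_o, 0)
        with pytest.raises(ValueError):
            ns.run_initialization_ensemble(fan, D_o, 1, budget="forever")

    def test_representative_state_closest_to_mean(self, unlimited_ensembles, D_o, stacked):
        ens = unlimited_ensembles[stacked.name]
        s1 = representative_state(ens, D_o)
        gap = abs(ens.errors - ens.errors.mean())
        assert abs(s1.E_o_star - ens.errors.mean()) == pytest.approx(gap.min())


class TestExperimentConfig:
    def test_counts_validated(self):
        with pytest.raises(ValueError):
            ns.ExperimentConfig(n_trials=0)

    def test_limited_budget_below_cap(self):
        with pytest.raises(ValueError):
            ns.ExperimentConfig(limited_budget=60_000)
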