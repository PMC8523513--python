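"""Cognitive dynamics, the decision rule and the episodic environment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jitaisim import (CognitiveState, NotificationEnv, SimulatorConfig,
                      base_action_probability, decision_probability,
                      update_memory, update_urge)
from jitaisim.behavior import EnvState
from jitaisim.context import ContextVector


class TestCognitiveUpdates:
    @pytest.mark.parametrize("m_prev, notified, sigma, expected", [
        (0.5, 1, 0.8, 1.0),     # a notification restores full accessibility
        (0.5, 0, 0.8, 0.4),     # otherwise geometric decay
        (1.0, 0, 0.8, 0.8),
    ])
    def test_memory_rule(self, m_prev, notified, sigma, expected):
        assert update_memory(m_prev, notified, sigma) == pytest.approx(expected)

    def test_memory_decay_is_geometric_and_positive(self):
        m = 1.0
        for k in range(1, 40):
            m = update_memory(m, 0, 0.8)
            assert m == pytest.approx(0.8 ** k)
            assert m > 0

    @pytest.mark.parametrize("u_prev, acted, mu, expected", [
        (0.3, 1, 0.05, 0.0),    # a run resets the urge
        (0.3, 0, 0.05, 0.35),   # otherwise linear recovery
        (0.98, 0, 0.05, 1.0),   # capped at 1
    ])
    def test_urge_rule(self, u_prev, acted, mu, expected):
        assert update_urge(u_prev, acted, mu) == pytest.approx(expected)

    @given(m=st.floats(0.0, 1.0, exclude_min=True),
           u=st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_updates_stay_in_unit_interval(self, m, u):
        for notified in (0, 1):
            assert 0.0 < update_memory(m, notified, 0.8) <= 1.0
        for acted in (0, 1):
            assert 0.0 <= update_urge(u, acted, 0.05) <= 1.0

    @pytest.mark.parametrize("m, u, expected", [
        (0.7, 0.0, 0.0),        # no urge, no action
        (1.0, 1.0, 1.0),        # both maximal
        (0.8, 0.5, 0.4),        # product form
        (0.0, 0.9, 0.0),        # no memory, no action
    ])
    def test_base_action_probability(self, m, u, expected):
        assert base_action_probability(m, u) == pytest.approx(expected)


def _state(memory=0.5, urge=0.5, last_action=0,
           hour=12.0, weekday="Mon"):
    ctx = ContextVector(hour, weekday, 10.0, "clear", "calm", "low")
    return EnvState(clock=0, context=ctx,
                    cognitive=CognitiveState(memory, urge),
                    last_action=last_action, notifications_used=0,
                    hours_since_last_run=24.0, step_index=0, done=False)


def _delta_grid_oracle(state, notified, ratio, cfg, grid=512):
    """Brute-force marginalization over a discretized (M, U) grid.

    The DBN's latent transitions are point masses, so the double sum over a
    grid holding those masses must collapse to the single surviving term.
    """
    m_star = update_memory(state.cognitive.memory, notified, cfg.sigma)
    u_star = update_urge(state.cognitive.urge, state.last_action, cfg.mu)
    m_grid = np.unique(np.concatenate([np.linspace(1e-9, 1, grid), [m_star]]))
    u_grid = np.unique(np.concatenate([np.linspace(0, 1, grid), [u_star]]))
    total = 0.0
    for m in m_grid:
        p_m = 1.0 if m == m_star else 0.0
        if p_m == 0.0:
            continue
        for u in u_grid:
            p_u = 1.0 if u == u_star else 0.0
            total += ratio * base_action_probability(m, u) * p_m * p_u
    return min(1.0, max(0.0, total))


class TestDecisionProbability:
    def test_neutral_context_reduces_to_base_probability(self, sim_config):
        st_ = _state(memory=0.5, urge=0.6, last_action=0)
        p = decision_probability(st_, 1, None, None, sim_config, ratio=1.0)
        m_t = update_memory(0.5, 1, sim_config.sigma)
        u_t = update_urge(0.6, 0, sim_config.mu)
        assert p == pytest.approx(base_action_probability(m_t, u_t))

    def test_large_ratio_clamps_to_one(self, sim_config):
        st_ = _state(memory=1.0, urge=0.9)
        assert decision_probability(st_, 1, None, None, sim_config,
                                    ratio=50.0) == 1.0

    def test_matches_delta_grid_oracle_on_random_states(self, sim_config):
        rng = np.random.default_rng(314)
        for _ in range(100):
            st_ = _state(memory=float(rng.uniform(1e-6, 1)),
                         urge=float(rng.uniform(0, 1)),
                         last_action=int(rng.integers(2)))
            notified = int(rng.integers(2))
            ratio = float(rng.uniform(0, 20))
            p = decision_probability(st_, notified, None, None, sim_config,
                                     ratio=ratio)
            assert p == pytest.approx(
                _delta_grid_oracle(st_, notified, ratio, sim_config),
                abs=1e-12)

    def test_notification_never_decreases_probability(self, sim_config):
        rng = np.random.default_rng(99)
        for _ in range(50):
            st_ = _state(memory=float(rng.uniform(1e-6, 1)),
                         urge=float(rng.uniform(0, 1)))
            ratio = float(rng.uniform(0, 5))
            p0 = decision_probability(st_, 0, None, None, sim_config, ratio=ratio)
            p1 = decision_probability(st_, 1, None, None, sim_config, ratio=ratio)
            assert p1 >= p0


@pytest.fixture(scope="module")
def env(fitted_models, small_world, sim_config):
    cond, prior = fitted_models
    _, stream = small_world
    return NotificationEnv(stream, cond, prior, sim_config, rng=7)


class TestEnvironment:
    def test_seeded_reset_is_deterministic(self, env):
        s1 = env.reset(seed=123)
        s2 = env.reset(seed=123)
        assert s1.clock == s2.clock
        assert s1.cognitive.memory == s2.cognitive.memory
        assert s1.context == s2.context

    def test_reset_lands_on_first_decision_hour(self, env, sim_config):
        s = env.reset(seed=5)
        assert s.context.hour == sim_config.decision_hours[0]

    def test_overnight_decay_from_midnight(self, env, sim_config):
        s = env.reset(seed=5)
        expected = sim_config.initial_memory * sim_config.sigma ** 8
        assert s.cognitive.memory == pytest.approx(expected)

    def test_episode_has_91_steps(self, env):
        s = env.reset(seed=11)
        n = 0
        while not s.done:
            s, _, done, _ = env.step(0)
            n += 1
        assert n == 91
        assert len(env.episode_trace()) == 91

    def test_step_after_done_raises(self, env):
        s = env.reset(seed=11)
        while not s.done:
            s, _, _, _ = env.step(0)
        with pytest.raises(RuntimeError):
            env.step(0)

    def test_latents_stay_in_bounds_along_trajectory(self, env):
        rng = np.random.default_rng(2)
        s = env.reset(seed=21)
        while not s.done:
            s, _, _, info = env.step(int(rng.integers(2)))
            assert 0.0 < s.cognitive.memory <= 1.0
            assert 0.0 <= s.cognitive.urge <= 1.0
            assert 0.0 <= info["p_run"] <= 1.0

    def test_memory_resets_on_notification_and_decays_between(self, env):
        env.reset(seed=31)
        env.step(1)
        trace_row = env._trace[-1]
        assert trace_row[5] == 1.0                      # memory column
        m_prev = 1.0
        for _ in range(5):
            env.step(0)
            m = env._trace[-1][5]
            assert m < m_prev
            m_prev = m

    def test_urge_is_zero_the_step_after_a_run(self, env, monkeypatch):
        env.reset(seed=41)
        # force a run by making every context maximally desirable
        monkeypatch.setattr(env, "desirability",
                            np.full_like(env.desirability, 100.0))
        env.step(1)
        assert env._trace[-1][7] == 1                   # action column
        env.step(0)
        assert env._trace[-1][6] == 0.0                 # urge column

    def test_urge_nondecreasing_between_runs(self, env):
        env.reset(seed=51)
        prev = None
        for _ in range(13):                             # one day, same-day steps
            env.step(0)
            _, _, _, _, _, _, urge, action, _, _ = env._trace[-1]
            if prev is not None and not ran_prev:
                assert urge >= prev
            prev, ran_prev = urge, bool(action)

    def test_env_side_budget_suppression(self, fitted_models, small_world,
                                         sim_config):
        cond, prior = fitted_models
        _, stream = small_world
        env = NotificationEnv(stream, cond, prior, sim_config,
                              enforce_budget=True, rng=3)
        s = env.reset(seed=77)
        delivered = 0
        while not s.done:
            s, _, _, info = env.step(1)                 # always ask to send
            delivered += info["delivered"]
        assert delivered == sim_config.budget
        assert s.notifications_used == sim_config.budget

    def test_short_stream_rejected(self, fitted_models, small_world):
        cond, prior = fitted_models
        _, stream = small_world
        with pytest.raises(ValueError):
            NotificationEnv(stream.head(50), cond, prior)

    def test_reward_equals_one_when_user_runs(self, env, monkeypatch):
        env.reset(seed=61)
        monkeypatch.setattr(env, "desirability",
                            np.full_like(env.desirability, 100.0))
        _, reward, _, info = env.step(1)                # p_run = 1 here
        assert info["p_run"] == 1.0
        assert reward == 1.0

    def test_expected_reward_matches_analytic_rate(self, fitted_models,
                                                   small_world, sim_config):
        """With ratio == 1 the per-step run rate is u_t * m_t exactly."""
        cond, prior = fitted_models
        _, stream = small_world
        env = NotificationEnv(stream, cond, prior, sim_config, rng=9)
        env.desirability = np.ones_like(env.desirability)
        n, hits, expected = 0, 0, 0.0
        while n < 10_000:
            s = env.reset()
            while not s.done and n < 10_000:
                s, r, _, info = env.step(1 if n % 7 == 0 else 0)
                expected += info["p_run"]
                hits += r
                n += 1
        se = np.sqrt(max(expected, 1.0))            # Poisson-binomial scale
        assert abs(hits - expected) < 3 * se
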