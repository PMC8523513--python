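"""Notification agents: the budget-restricted REINFORCE learner and rule-based baselines.

The learner is Monte-Carlo policy gradient (REINFORCE) with a per-step
baseline: after each weekly episode it takes one gradient-ascent step on

    J(theta) = sum_t  log pi_theta(a_t | o_t) * (G_t - Gbar_t)

where ``G_t`` is the return from step ``t`` (discount ``gamma``, default 1)
and ``Gbar_t`` averages the returns at step position ``t`` over the past
``n`` episodes.  The policy is a small feed-forward network (one tanh hidden
layer, softmax over {no-send, send}) implemented directly in numpy with
hand-derived gradients; a finite-difference test pins them down.

The weekly notification budget is respected in one of three modes:

* **R** — agent-side clipping: once the budget is spent the send
  probability is forced to 0; forced steps are excluded from the gradient.
* **C** — the agent samples freely and the environment suppresses
  over-budget notifications.
* **B** — unrestricted until ``switch_episode``, then environment-side
  suppression as in C.

The agent observes the encoded context (one-hot categories, normalized
hour and temperature, the fitted models' desirability at that context),
its remaining budget, the hours since the user's last run and the episode
progress — never the user's latent memory or urge.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .behavior import EnvState, NotificationEnv, SimulatorConfig

#: Cap (hours) on the hours-since-last-run observation feature.
HOURS_SINCE_RUN_CAP = 48.0


# ---------------------------------------------------------------------------
# Observation encoding
# ---------------------------------------------------------------------------

class ObservationEncoder:
    """Encode an environment state into a fixed-length feature vector.

    Layout: one-hot weekday (7) | one-hot weather | one-hot wind | one-hot
    humidity | hour scaled to [0, 1] | temperature / 30 | log10 context
    desirability / 2 | remaining budget fraction | hours-since-last-run /
    cap (capped at 1) | episode progress (step index / episode length).

    The context desirability (the likelihood ratio of the system's own
    fitted context models) is part of the encoded context: the notification
    system built those models from historical data, so their value at the
    current context is knowledge the agent legitimately holds.  The last
    three features make the reported strategies representable: spreading a
    budget requires knowing both how much budget and how much episode
    remain (episodes start on a random date, so the weekday alone does not
    encode episode position), and "don't notify right after a run" requires
    run recency.  The user's latent memory and urge are never observed.
    """

    def __init__(self, level_sets: dict[str, list[str]], cfg: SimulatorConfig,
                 cond=None, prior=None):
        self.cfg = cfg
        self.cond = cond
        self.prior = prior
        self.weekdays = list(level_sets["weekday"])
        self.weather = list(level_sets["weather"])
        self.wind = list(level_sets["wind"])
        self.humidity = list(level_sets["humidity"])
        self.dim = (len(self.weekdays) + len(self.weather) + len(self.wind)
                    + len(self.humidity) + 6)

    @staticmethod
    def _log_desirability(ratio: float | np.ndarray):
        return np.log10(np.clip(ratio, 1e-3, None)) / 2.0

    def encode(self, state: EnvState, remaining_budget: int) -> np.ndarray:
        c = state.context
        x = np.zeros(self.dim)
        off = 0
        for levels, value in ((self.weekdays, c.weekday),
                              (self.weather, c.weather),
                              (self.wind, c.wind),
                              (self.humidity, c.humidity)):
            if value in levels:
                x[off + levels.index(value)] = 1.0
            off += len(levels)
        x[off] = c.hour / 24.0
        x[off + 1] = c.temperature / 30.0
        if self.cond is not None and self.prior is not None:
            from .context import likelihood_ratio
            x[off + 2] = self._log_desirability(
                likelihood_ratio(self.cond, self.prior, c))
        x[off + 3] = max(remaining_budget, 0) / max(self.cfg.budget, 1)
        hsr = min(state.hours_since_last_run, HOURS_SINCE_RUN_CAP)
        x[off + 4] = hsr / HOURS_SINCE_RUN_CAP
        x[off + 5] = state.step_index / self.cfg.steps_per_episode
        return x

    def encode_stream(self, env: NotificationEnv) -> np.ndarray:
        """Static (context-only) feature rows for every hour of the stream.

        The two dynamic entries (budget, hours-since-run) are left zero and
        filled in per step; precomputing the rest makes training cheap.
        """
        stream = env.stream
        n = len(stream)
        x = np.zeros((n, self.dim))
        off = 0
        for levels, col in ((self.weekdays, "weekday"),
                            (self.weather, "weather"),
                            (self.wind, "wind"),
                            (self.humidity, "humidity")):
            codes = stream[col].map({v: i for i, v in enumerate(levels)})
            valid = codes.notna().to_numpy()
            x[np.flatnonzero(valid), off + codes[valid].astype(int).to_numpy()] = 1.0
            off += len(levels)
        x[:, off] = stream["hour"].to_numpy(float) / 24.0
        x[:, off + 1] = stream["temperature"].to_numpy(float) / 30.0
        x[:, off + 2] = self._log_desirability(env.desirability)
        return x

    def fill_dynamic(self, row: np.ndarray, remaining_budget: int,
                     hours_since_last_run: float, step_index: int) -> np.ndarray:
        x = row.copy()
        x[-3] = max(remaining_budget, 0) / max(self.cfg.budget, 1)
        x[-2] = min(hours_since_last_run, HOURS_SINCE_RUN_CAP) / HOURS_SINCE_RUN_CAP
        x[-1] = step_index / self.cfg.steps_per_episode
        return x


# ---------------------------------------------------------------------------
# Policy network and REINFORCE
# ---------------------------------------------------------------------------

class PolicyNetwork:
    """One-hidden-layer tanh network with a softmax over {no-send, send}."""

    def __init__(self, input_dim: int, hidden: int = 64,
                 learning_rate: float = 0.001,
                 rng: np.random.Generator | int | None = None):
        rng = np.random.default_rng(rng)
        self.input_dim = input_dim
        self.hidden = hidden
        self.learning_rate = learning_rate
        self.W1 = rng.normal(0.0, 1.0 / np.sqrt(input_dim), (input_dim, hidden))
        self.b1 = np.zeros(hidden)
        self.W2 = rng.normal(0.0, 1.0 / np.sqrt(hidden), (hidden, 2))
        self.b2 = np.zeros(2)

    # forward ---------------------------------------------------------------

    def probs(self, x: np.ndarray) -> np.ndarray:
        """Action probabilities; accepts a single observation or a batch."""
        h = np.tanh(x @ self.W1 + self.b1)
        logits = h @ self.W2 + self.b2
        logits = logits - logits.max(axis=-1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=-1, keepdims=True)

    # gradient --------------------------------------------------------------

    def objective(self, X: np.ndarray, actions: np.ndarray,
                  advantages: np.ndarray) -> float:
        p = self.probs(X)
        logp = np.log(p[np.arange(len(actions)), actions])
        return float(np.sum(logp * advantages))

    def gradients(self, X: np.ndarray, actions: np.ndarray,
                  advantages: np.ndarray):
        """Analytic gradient of ``sum_t logp(a_t) * adv_t`` w.r.t. parameters."""
        h = np.tanh(X @ self.W1 + self.b1)
        logits = h @ self.W2 + self.b2
        logits = logits - logits.max(axis=-1, keepdims=True)
        e = np.exp(logits)
        p = e / e.sum(axis=-1, keepdims=True)
        dlogits = -p * advantages[:, None]
        dlogits[np.arange(len(actions)), actions] += advantages
        gW2 = h.T @ dlogits
        gb2 = dlogits.sum(axis=0)
        dh = (dlogits @ self.W2.T) * (1.0 - h * h)
        gW1 = X.T @ dh
        gb1 = dh.sum(axis=0)
        return gW1, gb1, gW2, gb2

    def ascend(self, X: np.ndarray, actions: np.ndarray,
               advantages: np.ndarray) -> None:
        """One stochastic gradient-ascent step at the configured learning rate."""
        with np.errstate(invalid="ignore", over="ignore"):
            grads = self.gradients(X, actions, advantages)
        for g in grads:
            if not np.all(np.isfinite(g)):
                raise FloatingPointError(
                    "non-finite policy gradient; advantages="
                    f"[{advantages.min():.3g}, {advantages.max():.3g}]")
        gW1, gb1, gW2, gb2 = grads
        a = self.learning_rate
        self.W1 += a * gW1
        self.b1 += a * gb1
        self.W2 += a * gW2
        self.b2 += a * gb2

    # persistence ------------------------------------------------------------

    def state_dict(self) -> dict:
        return {"W1": self.W1.tolist(), "b1": self.b1.tolist(),
                "W2": self.W2.tolist(), "b2": self.b2.tolist(),
                "learning_rate": self.learning_rate}

    def load_state_dict(self, d: dict) -> None:
        self.W1 = np.asarray(d["W1"], float)
        self.b1 = np.asarray(d["b1"], float)
        self.W2 = np.asarray(d["W2"], float)
        self.b2 = np.asarray(d["b2"], float)
        self.learning_rate = d["learning_rate"]
        self.input_dim, self.hidden = self.W1.shape


class BaselineBuffer:
    """Per-step-position average of the returns from the past ``n`` episodes."""

    def __init__(self, steps_per_episode: int, n_episodes: int = 50):
        self.steps = steps_per_episode
        self.buffer: deque[np.ndarray] = deque(maxlen=n_episodes)

    def baseline(self) -> np.ndarray:
        if not self.buffer:
            return np.zeros(self.steps)
        return np.mean(np.stack(self.buffer), axis=0)

    def append(self, returns: np.ndarray) -> None:
        if len(returns) != self.steps:
            raise ValueError("returns length does not match the episode length")
        self.buffer.append(np.asarray(returns, float))


def compute_returns(rewards, gamma: float) -> np.ndarray:
    """Discounted returns ``G_t = sum_{k>=t} gamma^(k-t) r_k``."""
    r = np.asarray(rewards, float)
    out = np.empty_like(r)
    acc = 0.0
    for t in range(len(r) - 1, -1, -1):
        acc = r[t] + gamma * acc
        out[t] = acc
    return out


def reinforce_update(policy: PolicyNetwork, observations: np.ndarray,
                     actions: np.ndarray, rewards: np.ndarray,
                     forced: np.ndarray, baseline: BaselineBuffer,
                     gamma: float = 1.0) -> np.ndarray:
    """One REINFORCE-with-baseline episode update; returns the episode's G_t.

    Forced no-send steps (R-mode with the budget spent) carry no
    log-probability and are excluded from the gradient.
    """
    returns = compute_returns(rewards, gamma)
    adv = returns - baseline.baseline()
    free = ~np.asarray(forced, bool)
    if free.any():
        policy.ascend(observations[free], np.asarray(actions)[free], adv[free])
    baseline.append(returns)
    return returns


# ---------------------------------------------------------------------------
# Agents
# ---------------------------------------------------------------------------

@dataclass
class StepRecord:
    observation: np.ndarray
    action: int
    forced: bool


class ReinforceAgent:
    """REINFORCE learner in restriction mode ``R``, ``C`` or ``B``."""

    learns = True

    def __init__(self, encoder: ObservationEncoder, mode: str = "R",
                 hidden: int = 64, learning_rate: float = 0.001,
                 gamma: float = 1.0, baseline_episodes: int = 50,
                 switch_episode: int | None = None,
                 rng: np.random.Generator | int | None = None):
        if mode not in ("R", "C", "B"):
            raise ValueError(f"unknown restriction mode {mode!r}")
        if mode == "B" and switch_episode is None:
            raise ValueError("B mode requires switch_episode")
        self.encoder = encoder
        self.mode = mode
        self.switch_episode = switch_episode
        self.rng = np.random.default_rng(rng)
        self.policy = PolicyNetwork(encoder.dim, hidden=hidden,
                                    learning_rate=learning_rate, rng=self.rng)
        self.gamma = gamma
        self.baseline = BaselineBuffer(encoder.cfg.steps_per_episode,
                                       baseline_episodes)
        self.episode_index = 0
        self._records: list[StepRecord] = []

    # environment-side restriction applies in C always, in B after the switch
    def env_enforces_budget(self) -> bool:
        if self.mode == "C":
            return True
        if self.mode == "B":
            return self.episode_index >= self.switch_episode
        return False

    def begin_episode(self) -> None:
        self._records = []

    def select_action(self, observation: np.ndarray,
                      remaining_budget: int) -> int:
        """Sample send/no-send; in R mode a spent budget forces no-send."""
        if self.mode == "R" and remaining_budget <= 0:
            self._records.append(StepRecord(observation, 0, True))
            return 0
        p_send = self.policy.probs(observation)[1]
        action = int(self.rng.random() < p_send)
        self._records.append(StepRecord(observation, action, False))
        return action

    def finish_episode(self, rewards) -> np.ndarray:
        X = np.stack([r.observation for r in self._records])
        actions = np.array([r.action for r in self._records])
        forced = np.array([r.forced for r in self._records])
        returns = reinforce_update(self.policy, X, actions, np.asarray(rewards),
                                   forced, self.baseline, self.gamma)
        self.episode_index += 1
        return returns


class RuleBasedAgent:
    """Context-blind baseline: random-week, random-day or fixed schedules."""

    learns = False
    FIXED_HOURS = (12, 16)

    def __init__(self, kind: str, cfg: SimulatorConfig,
                 rng: np.random.Generator | int | None = None):
        if kind not in ("random_week", "random_day", "fixed"):
            raise ValueError(f"unknown baseline agent kind {kind!r}")
        self.kind = kind
        self.cfg = cfg
        self.rng = np.random.default_rng(rng)
        self._schedule: set[int] = set()
        self._step = 0
        self.episode_index = 0

    def env_enforces_budget(self) -> bool:
        return False

    def begin_episode(self) -> None:
        cfg = self.cfg
        spd = cfg.steps_per_day
        if self.kind == "random_week":
            picks = self.rng.choice(cfg.steps_per_episode,
                                    size=min(cfg.budget, cfg.steps_per_episode),
                                    replace=False)
            self._schedule = set(int(i) for i in picks)
        elif self.kind == "random_day":
            self._schedule = set()
            for day in range(cfg.episode_days):
                picks = self.rng.choice(spd, size=2, replace=False)
                self._schedule.update(day * spd + int(i) for i in picks)
        else:  # fixed: every day at the same two hours
            idx = [cfg.decision_hours.index(h) for h in self.FIXED_HOURS]
            self._schedule = {day * spd + i
                              for day in range(cfg.episode_days) for i in idx}
        self._step = 0

    def select_action(self, observation, remaining_budget: int) -> int:
        action = int(self._step in self._schedule)
        self._step += 1
        return action

    def finish_episode(self, rewards) -> np.ndarray:
        self.episode_index += 1
        return compute_returns(rewards, 1.0)


def make_baseline_agent(kind: str, cfg: SimulatorConfig,
                        rng: np.random.Generator | int | None = None
                        ) -> RuleBasedAgent:
    return RuleBasedAgent(kind, cfg, rng)


def make_agent(name: str, encoder: ObservationEncoder,
               cfg: SimulatorConfig, rng=None,
               switch_episode: int | None = None, **kwargs):
    """Construct any agent by its experiment name (R, C, B or a baseline kind)."""
    if name in ("R", "C", "B"):
        return ReinforceAgent(encoder, mode=name, rng=rng,
                              switch_episode=switch_episode, **kwargs)
    return make_baseline_agent(name, cfg, rng)


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(agent: ReinforceAgent, path) -> None:
    import json
    payload = {
        "mode": agent.mode,
        "switch_episode": agent.switch_episode,
        "episode_index": agent.episode_index,
        "gamma": agent.gamma,
        "policy": agent.policy.state_dict(),
        "baseline": [b.tolist() for b in agent.baseline.buffer],
        "rng_state": agent.rng.bit_generator.state,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_checkpoint(path, encoder: ObservationEncoder) -> ReinforceAgent:
    import json
    with open(path) as fh:
        d = json.load(fh)
    agent = ReinforceAgent(encoder, mode=d["mode"],
                           switch_episode=d["switch_episode"],
                           gamma=d["gamma"])
    agent.policy.load_state_dict(d["policy"])
    for b in d["baseline"]:
        agent.baseline.append(np.asarray(b, float))
    agent.episode_index = d["episode_index"]
    agent.rng.bit_generator.state = d["rng_state"]
    return agent
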