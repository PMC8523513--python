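"""Stochastic user simulator: cognitive dynamics and the weekly episodic environment.

The simulated user carries two latent determinants of the target activity
(running, by default):

* **memory accessibility** ``M`` — jumps to its maximum 1.0 when a
  notification arrives and otherwise decays geometrically, ``M_t = sigma *
  M_{t-1}`` with retention rate ``sigma`` per hour;
* **urge** ``U`` — resets to 0.0 the step after a run and otherwise recovers
  linearly, ``U_t = min(1, U_{t-1} + mu)`` with recovery rate ``mu`` per hour.

Both transitions are deterministic (Kronecker-delta conditionals in the
underlying dynamic Bayesian network).  The probability that the user runs in
the current hour couples the latent state with the observable context
through the context-desirability likelihood ratio:

    P(A_t = 1) = clamp( LR(C_t) * U_t * M_t , 0, 1 )

where ``LR(C) = P(C | A=1) / P(C)`` comes from :mod:`jitaisim.context`.

Episodes are weeks.  The agent decides whether to notify at every hour from
8:00 to 20:00 (13 decisions/day, 91/week); a run within the hour yields
reward 1.0.  Overnight the simulator applies one (decay, growth,
no-decision) update per skipped hour, so ``sigma`` and ``mu`` keep their
per-hour meaning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .context import (ContextDistributionModel, ContextVector,
                      likelihood_ratio_profile, RATIO_MAX)

TRACE_COLUMNS = ["step", "clock", "hour", "weekday", "notification",
                 "memory", "urge", "action", "reward", "desirability"]


@dataclass
class CognitiveState:
    """Latent user state; memory in (0, 1], urge in [0, 1]."""

    memory: float
    urge: float


@dataclass(frozen=True)
class SimulatorConfig:
    sigma: float = 0.8                 # memory retention rate, per hour
    mu: float = 0.05                   # urge recovery rate, per hour
    decision_hours: tuple[int, ...] = tuple(range(8, 21))
    episode_days: int = 7
    budget: int = 14                   # notifications per episode
    reward_per_run: float = 1.0
    initial_memory: float = 0.5
    initial_urge: float = 0.5
    ratio_max: float = RATIO_MAX

    def __post_init__(self):
        if not 0.0 < self.sigma < 1.0:
            raise ValueError("sigma must lie in (0, 1)")
        if not 0.0 < self.mu < 1.0:
            raise ValueError("mu must lie in (0, 1)")
        if self.budget < 0:
            raise ValueError("budget must be nonnegative")
        hours = self.decision_hours
        if any(b <= a for a, b in zip(hours, hours[1:])) or \
                hours[0] < 0 or hours[-1] > 23:
            raise ValueError("decision_hours must be strictly increasing in 0..23")

    @property
    def steps_per_day(self) -> int:
        return len(self.decision_hours)

    @property
    def steps_per_episode(self) -> int:
        return self.episode_days * self.steps_per_day


@dataclass
class EnvState:
    """Environment-side state at one decision point.

    ``cognitive`` holds the previous hour's (M, U); the step applies the
    current hour's transition itself.  ``last_action`` is the user's most
    recent run decision, consumed by the urge update.
    """

    clock: int                       # absolute hour index into the stream
    context: ContextVector
    cognitive: CognitiveState
    last_action: int
    notifications_used: int
    hours_since_last_run: float
    step_index: int
    done: bool


def update_memory(m_prev: float, notified: int, sigma: float) -> float:
    """One hourly memory transition: reset to 1.0 on a notification, else decay."""
    if not 0.0 < m_prev <= 1.0:
        raise ValueError(f"memory must lie in (0, 1], got {m_prev}")
    return 1.0 if notified else sigma * m_prev


def update_urge(u_prev: float, acted_prev: int, mu: float) -> float:
    """One hourly urge transition: reset to 0.0 after a run, else grow, capped."""
    if not 0.0 <= u_prev <= 1.0:
        raise ValueError(f"urge must lie in [0, 1], got {u_prev}")
    return 0.0 if acted_prev else min(1.0, u_prev + mu)


def base_action_probability(m: float, u: float) -> float:
    """P(A=1 | U, M) = U * M: zero without urge or memory, 1 when both are maximal."""
    return u * m


def decision_probability(state: EnvState, notified: int,
                         cond: ContextDistributionModel,
                         prior: ContextDistributionModel,
                         cfg: SimulatorConfig,
                         ratio: float | None = None) -> float:
    """Probability the user runs this hour given the notification decision.

    Applies the hour's deterministic (M, U) transitions to the state carried
    in ``state.cognitive``, then weights U*M by the context likelihood ratio
    and clamps into [0, 1].  Because the latent transitions are point masses,
    the marginalization over (M_t, U_t) collapses to this single term.
    """
    from .context import likelihood_ratio
    m_t = update_memory(state.cognitive.memory, notified, cfg.sigma)
    u_t = update_urge(state.cognitive.urge, state.last_action, cfg.mu)
    if ratio is None:
        ratio = likelihood_ratio(cond, prior, state.context,
                                 ratio_max=cfg.ratio_max)
    return float(np.clip(ratio * base_action_probability(m_t, u_t), 0.0, 1.0))


class NotificationEnv:
    """Weekly episodic environment in the conventional reset/step interface.

    Parameters
    ----------
    stream
        Hourly weather DataFrame (columns ``timestamp, hour, weekday,
        temperature, weather, wind, humidity``), the environment's source of
        real-world context.
    cond, prior
        Fitted context models for P(C|A=1) and P(C); their likelihood ratio
        is precomputed for every stream row at construction.
    enforce_budget
        If True the environment suppresses notifications beyond the budget
        (C-mode restriction); if False delivery is up to the agent (R-mode).
    """

    action_space = (0, 1)

    def __init__(self, stream: pd.DataFrame,
                 cond: ContextDistributionModel,
                 prior: ContextDistributionModel,
                 cfg: SimulatorConfig = SimulatorConfig(),
                 enforce_budget: bool = False,
                 rng: np.random.Generator | int | None = None):
        self.cfg = cfg
        self.cond = cond
        self.prior = prior
        self.enforce_budget = enforce_budget
        self.rng = np.random.default_rng(rng)
        self.stream = stream.reset_index(drop=True)
        hours = self.stream["hour"].to_numpy()
        if len(self.stream) < cfg.episode_days * 24:
            raise ValueError("weather stream shorter than one episode")
        self.desirability = likelihood_ratio_profile(
            cond, prior, self.stream, ratio_max=cfg.ratio_max)
        # plain-list column caches: row access in the step loop is hot
        self._hours = self.stream["hour"].astype(float).tolist()
        self._weekdays = self.stream["weekday"].tolist()
        self._temps = self.stream["temperature"].astype(float).tolist()
        self._weathers = self.stream["weather"].tolist()
        self._winds = self.stream["wind"].tolist()
        self._humids = self.stream["humidity"].tolist()
        # admissible episode starts: midnight rows with a full episode ahead
        self._starts = np.flatnonzero(
            (hours == 0)
            & (np.arange(len(hours)) + cfg.episode_days * 24 <= len(hours)))
        if len(self._starts) == 0:
            raise ValueError("weather stream shorter than one episode")
        self.state: EnvState | None = None
        self._trace: list[tuple] | None = None

    # -- helpers -----------------------------------------------------------

    def _context_at(self, clock: int) -> ContextVector:
        return ContextVector(hour=self._hours[clock],
                             weekday=self._weekdays[clock],
                             temperature=self._temps[clock],
                             weather=self._weathers[clock],
                             wind=self._winds[clock],
                             humidity=self._humids[clock])

    def _hourly_skip(self, cog: CognitiveState, hours: int) -> CognitiveState:
        """No-decision, no-notification updates for skipped (overnight) hours."""
        m, u = cog.memory, cog.urge
        for _ in range(hours):
            m = self.cfg.sigma * m
            u = min(1.0, u + self.cfg.mu)
        return CognitiveState(memory=m, urge=u)

    # -- episodic interface ------------------------------------------------

    def reset(self, seed: int | None = None) -> EnvState:
        """Start an episode at 0:00 of a random stream date.

        The cognitive state is initialized at midnight and advanced through
        the overnight hours to the first decision hour, one decay/growth
        update per hour.
        """
        if seed is not None:
            self.rng = np.random.default_rng(seed)
        cfg = self.cfg
        start = int(self.rng.choice(self._starts))
        first_hour = cfg.decision_hours[0]
        cog = self._hourly_skip(
            CognitiveState(cfg.initial_memory, cfg.initial_urge), first_hour)
        clock = start + first_hour
        self.state = EnvState(clock=clock, context=self._context_at(clock),
                              cognitive=cog, last_action=0,
                              notifications_used=0,
                              hours_since_last_run=float("inf"),
                              step_index=0, done=False)
        self._episode_start = start
        self._trace = []
        return self.state

    def step(self, action: int):
        """Advance one decision point; returns (state, reward, done, info)."""
        st = self.state
        if st is None or st.done:
            raise RuntimeError("step() called on a finished or unreset environment")
        cfg = self.cfg

        # 1. delivery, possibly suppressed by the environment-side restriction
        delivered = int(action)
        if self.enforce_budget and st.notifications_used >= cfg.budget:
            delivered = 0

        # 2-3. deterministic cognitive transitions for this hour
        m_t = update_memory(st.cognitive.memory, delivered, cfg.sigma)
        u_t = update_urge(st.cognitive.urge, st.last_action, cfg.mu)

        # 4. the user's run decision
        ratio = float(self.desirability[st.clock])
        p_run = min(1.0, ratio * base_action_probability(m_t, u_t))
        a_t = int(self.rng.random() < p_run)

        # 5. reward
        reward = cfg.reward_per_run * a_t

        ctx = st.context
        self._trace.append((st.step_index, st.clock, ctx.hour, ctx.weekday,
                            delivered, m_t, u_t, a_t, reward, ratio))

        used = st.notifications_used + delivered
        hsr = 0.0 if a_t else st.hours_since_last_run
        step_index = st.step_index + 1
        done = step_index >= cfg.steps_per_episode

        cog = CognitiveState(memory=m_t, urge=u_t)
        clock = st.clock
        if not done:
            # 6. advance to the next decision hour, applying one hourly
            #    update per strictly-skipped hour (overnight: 11 of them,
            #    the in-step transition above being the 12th).
            day_pos = step_index % cfg.steps_per_day
            if day_pos == 0:
                gap = 24 - cfg.decision_hours[-1] + cfg.decision_hours[0]
            else:
                gap = cfg.decision_hours[day_pos] - cfg.decision_hours[day_pos - 1]
            cog = self._hourly_skip(cog, gap - 1)
            hsr = hsr + gap if np.isfinite(hsr) else hsr
            clock = clock + gap
            # a run during the skipped hours is impossible (no decisions);
            # the urge reset for a_t happens in the next step's update.
            last_action = a_t
            context = self._context_at(clock)
        else:
            last_action = a_t
            context = ctx

        self.state = EnvState(clock=clock, context=context, cognitive=cog,
                              last_action=last_action,
                              notifications_used=used,
                              hours_since_last_run=hsr,
                              step_index=step_index, done=done)
        info = {"p_run": p_run, "desirability": ratio, "delivered": delivered,
                "notifications_used": used}
        return self.state, reward, done, info

    def episode_trace(self) -> pd.DataFrame:
        """Per-step record of the current (or just finished) episode."""
        return pd.DataFrame(self._trace or [], columns=TRACE_COLUMNS)


def save_trace(trace: pd.DataFrame, path) -> None:
    trace.to_csv(path, index=False)


def load_trace(path) -> pd.DataFrame:
    return pd.read_csv(path)
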