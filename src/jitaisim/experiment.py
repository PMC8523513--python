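"""Experiment orchestration: training runs, learning curves and episode plots.

Reproduces the two comparisons the simulator was built for, at configurable
scale:

* **context-aware vs. rule-based** — the budget-restricted REINFORCE agent
  (R) against the random-week, random-day and fixed schedules, all sending
  the same number of notifications per weekly episode;
* **restriction modes** — R (agent-side clipping) vs. C (environment-side
  suppression) vs. B (unrestricted until a switch episode, then
  suppressed).

Within one repetition every agent shares a single environment
initialization — the same weather stream, the same random start dates, the
same environment RNG seed — so curves differ only through the agents'
policies and their own RNG streams.  Learning curves are reported as
trailing means over a sliding window of episodes (default 500).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .agents import ObservationEncoder, make_agent
from .behavior import NotificationEnv, SimulatorConfig
from .context import ContextDistributionModel

CURVE_COLUMNS = ["episode", "agent", "seed", "reward", "notifications"]
WINDOW_COLUMNS = ["window_end", "agent", "seed", "mean_reward"]


@dataclass
class ExperimentConfig:
    episodes: int = 20_000
    repetitions: int = 20
    window: int = 500
    seeds: list[int] = field(default_factory=list)
    agents: list[str] = field(default_factory=lambda: [
        "R", "random_week", "random_day", "fixed"])
    switch_episode: int = 15_000        # B agents only
    simulator: SimulatorConfig = field(default_factory=SimulatorConfig)

    def __post_init__(self):
        if not self.seeds:
            self.seeds = list(range(self.repetitions))
        if len(self.seeds) != self.repetitions:
            raise ValueError("need exactly one seed per repetition")
        if self.window > self.episodes:
            raise ValueError("window must not exceed the episode count")


def sliding_window_average(values, window: int) -> np.ndarray:
    """Trailing mean over ``window`` entries, defined from index window-1 on."""
    if window < 1:
        raise ValueError("window must be >= 1")
    v = np.asarray(values, float)
    if window > len(v):
        return np.empty(0)
    c = np.concatenate([[0.0], np.cumsum(v)])
    return (c[window:] - c[:-window]) / window


def run_episode(env: NotificationEnv, agent, encoder: ObservationEncoder,
                static_features: np.ndarray):
    """Roll one episode; returns (total_reward, notifications, rewards)."""
    env.enforce_budget = agent.env_enforces_budget()
    state = env.reset()
    agent.begin_episode()
    cfg = env.cfg
    rewards = np.zeros(cfg.steps_per_episode)
    i = 0
    while not state.done:
        remaining = cfg.budget - state.notifications_used
        obs = encoder.fill_dynamic(static_features[state.clock], remaining,
                                   state.hours_since_last_run,
                                   state.step_index)
        action = agent.select_action(obs, remaining)
        state, reward, done, info = env.step(action)
        rewards[i] = reward
        i += 1
    agent.finish_episode(rewards)
    return float(rewards.sum()), state.notifications_used, rewards


def train_agent(env: NotificationEnv, agent, encoder: ObservationEncoder,
                episodes: int, static_features: np.ndarray | None = None
                ) -> pd.DataFrame:
    """Train (or just roll out) one agent; per-episode reward and notifications."""
    if static_features is None:
        static_features = encoder.encode_stream(env)
    out = np.empty((episodes, 2))
    for ep in range(episodes):
        total, used, _ = run_episode(env, agent, encoder, static_features)
        out[ep] = (total, used)
    return pd.DataFrame({"episode": np.arange(episodes),
                         "reward": out[:, 0],
                         "notifications": out[:, 1].astype(int)})


def run_training(cfg: ExperimentConfig,
                 stream: pd.DataFrame,
                 cond: ContextDistributionModel,
                 prior: ContextDistributionModel,
                 out_dir: str | Path | None = None,
                 progress: bool = False):
    """Run every agent for every repetition under a shared environment seed.

    Returns ``(curves, windows)``: per-episode rewards and the trailing
    window means, both in long format.  If ``out_dir`` is given the two CSVs
    plus a provenance sidecar JSON are written there.
    """
    encoder = ObservationEncoder(prior.level_sets, cfg.simulator, cond, prior)
    curves = []
    for rep, seed in enumerate(cfg.seeds):
        ss = np.random.SeedSequence(seed)
        env_seed, *agent_seeds = ss.spawn(1 + len(cfg.agents))
        for agent_name, agent_ss in zip(cfg.agents, agent_seeds):
            # all agents of a repetition share the environment seed, hence
            # the same start dates and user-decision randomness stream
            env = NotificationEnv(stream, cond, prior, cfg.simulator,
                                  rng=np.random.default_rng(env_seed))
            agent = make_agent(agent_name, encoder, cfg.simulator,
                               rng=np.random.default_rng(agent_ss),
                               switch_episode=cfg.switch_episode)
            static = encoder.encode_stream(env)
            df = train_agent(env, agent, encoder, cfg.episodes, static)
            df["agent"] = agent_name
            df["seed"] = seed
            curves.append(df)
            if progress:
                tail = df["reward"].tail(min(cfg.window, len(df))).mean()
                print(f"[rep {rep}] {agent_name}: "
                      f"final-{cfg.window} mean reward {tail:.3f}")
    curves = pd.concat(curves, ignore_index=True)[CURVE_COLUMNS]

    windows = []
    for (agent_name, seed), grp in curves.groupby(["agent", "seed"], sort=False):
        means = sliding_window_average(grp["reward"].to_numpy(), cfg.window)
        windows.append(pd.DataFrame({
            "window_end": np.arange(cfg.window - 1, cfg.episodes),
            "agent": agent_name, "seed": seed, "mean_reward": means}))
    windows = pd.concat(windows, ignore_index=True)[WINDOW_COLUMNS]

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        curves.to_csv(out / "episodes.csv", index=False)
        windows.to_csv(out / "window_means.csv", index=False)
        sidecar = {
            "episodes": cfg.episodes, "repetitions": cfg.repetitions,
            "window": cfg.window, "seeds": list(map(int, cfg.seeds)),
            "agents": list(cfg.agents), "switch_episode": cfg.switch_episode,
            "simulator": {
                "sigma": cfg.simulator.sigma, "mu": cfg.simulator.mu,
                "budget": cfg.simulator.budget,
                "decision_hours": list(cfg.simulator.decision_hours),
                "episode_days": cfg.simulator.episode_days,
            },
        }
        (out / "config.json").write_text(json.dumps(sidecar, indent=1))
    return curves, windows


def visualize_episode(trace: pd.DataFrame, quantile_bins: int = 5,
                      out_path: str | Path | None = None):
    """Hour-by-weekday episode map in the style of a policy-inspection plot.

    One circle per decision point, colored by the desirability (likelihood
    ratio) binned into ``quantile_bins`` diverging classes by within-episode
    quantiles; a black left half-marker flags a notification, a black right
    half-marker a run.  Returns ``(figure, table)`` where the table carries
    one row per decision point with its assigned color bin.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.markers import MarkerStyle

    tbl = trace.copy()
    des = tbl["desirability"].to_numpy(float)
    if np.allclose(des, des[0]):
        bins = np.full(len(des), quantile_bins // 2)
    else:
        qs = np.quantile(des, np.linspace(0, 1, quantile_bins + 1)[1:-1])
        bins = np.searchsorted(qs, des, side="right")
    tbl["desirability_bin"] = bins
    # day index from the step counter and the per-day schedule size
    steps_per_day = max(int(tbl["hour"].nunique()), 1)
    tbl["day"] = tbl["step"] // steps_per_day

    cmap = plt.get_cmap("RdBu_r", quantile_bins)
    fig, ax = plt.subplots(figsize=(8, 4))
    for _, row in tbl.iterrows():
        x, y = row["day"], row["hour"]
        ax.scatter(x, y, s=160, color=cmap(int(row["desirability_bin"])),
                   edgecolors="0.3", linewidths=0.5, zorder=2)
        if row["notification"]:
            ax.scatter(x, y, s=150, marker=MarkerStyle("o", fillstyle="left"),
                       color="black", zorder=3)
        if row["action"]:
            ax.scatter(x, y, s=150, marker=MarkerStyle("o", fillstyle="right"),
                       color="black", zorder=3)
    day_labels = tbl.drop_duplicates("day")["weekday"].tolist()
    ax.set_xticks(range(len(day_labels)), day_labels)
    ax.set_xlabel("weekday")
    ax.set_ylabel("hour of day")
    ax.set_title("episode map: color = context desirability, "
                 "left-half = notification, right-half = run")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
    return fig, tbl
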