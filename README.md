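# jitaisim

Simulation and reinforcement learning for **just-in-time adaptive
interventions** (JITAIs) in mobile health: when should an app send its
limited budget of notifications so that a user actually performs a target
activity (here: going for a run)?

The package provides:

* a **behavioral simulator** — a dynamic Bayesian network of a user whose
  *memory accessibility* `M` of the activity is maximized by a notification
  and decays geometrically (`M_t = σ·M_{t-1}`, σ = 0.8/h), whose *urge* `U`
  resets after a run and recovers linearly (`U_t = min(1, U_{t-1} + μ)`,
  μ = 0.05/h), and who runs with probability

  `P(A_t = 1) = clamp( LR(C_t) · U_t · M_t , 0, 1 )`,

  where `LR(C) = P(C | A=1) / P(C)` is the *context desirability* — how
  strongly the momentary context (hour, weekday, temperature, weather)
  favours running relative to baseline;
* **context-distribution fitting** — both densities share a factorized form
  (weekday categorical × weather-combination categorical × per-combination
  bivariate Gaussian over hour and temperature) fitted by maximum
  likelihood from an activity log and an hourly weather stream;
* a **budget-restricted REINFORCE agent** — Monte-Carlo policy gradient
  with a per-step baseline (mean return over the past 50 episodes),
  γ = 1, α = 0.001, deciding hourly from 8:00 to 20:00 whether to notify,
  under a hard cap of 14 notifications per weekly episode.  Three
  restriction modes (agent-side clipping **R**, environment-side
  suppression **C**, late-imposed restriction **B**) and three rule-based
  baselines (random-week, random-day, fixed at 12:00/16:00);
* a **synthetic-data generator** for both input datasets, so the entire
  pipeline runs from scratch with no external data.

## Worked example

```python
import numpy as np
import jitaisim as j

# 1. synthetic world: 10,000 activity records + 2 years of hourly weather
log, stream = j.generate_world(seed=1)

# 2. fit P(C|A=1) from the log and P(C) from the stream
cond = j.fit_context_distribution(log)
prior = j.fit_context_distribution(stream)

c = j.ContextVector(hour=18.0, weekday="Sat", temperature=15.0,
                    weather="clear", wind="calm", humidity="moderate")
print("desirability (clear Sat 18:00):", round(j.likelihood_ratio(cond, prior, c), 2))
c2 = j.ContextVector(hour=9.0, weekday="Tue", temperature=6.0,
                     weather="rain", wind="strong", humidity="high")
print("desirability (rainy Tue 9:00): ", round(j.likelihood_ratio(cond, prior, c2), 4))

# 3. environment + one week under the fixed 12:00/16:00 schedule
env = j.NotificationEnv(stream, cond, prior, rng=7)
enc = j.ObservationEncoder(prior.level_sets, env.cfg, cond, prior)
agent = j.make_baseline_agent("fixed", env.cfg, rng=3)
curve = j.train_agent(env, agent, enc, episodes=200)
print("fixed schedule, mean weekly runs:", round(curve["reward"].mean(), 2))
```

prints

```
desirability (clear Sat 18:00): 14.59
desirability (rainy Tue 9:00):  0.0287
fixed schedule, mean weekly runs: 11.98
```

A clear Saturday evening is ~15× over-represented among runs relative to
the weather prior; a rainy weekday morning is ~35× under-represented.  The
fixed 12:00/16:00 schedule earns ≈ 12 runs per simulated week.  Training
the restricted learner (`j.make_agent("R", enc, env.cfg, rng=...)` in the
same loop) starts near 9.5 and climbs steadily — past the random-week
schedule within a few thousand episodes and to random-day parity by
~25,000 — while a well-placed fixed schedule remains a strong opponent in
this synthetic world (docs/methods.md discusses why).  `j.run_training`
orchestrates the full multi-agent, multi-seed comparison with shared
environment initializations and writes the per-episode and
sliding-window-mean CSVs.

The same pipeline is scriptable from the shell:

```sh
jitaisim gen-data --out-dir data/ --seed 1
jitaisim fit-context --activity-log data/activity_log.csv --weather data/weather.csv --out models/ctx
jitaisim train --agent R --weather data/weather.csv --models models/ctx \
    --episodes 20000 --seed 0 --out-dir results/
jitaisim visualize --trace results/R_seed0_last_trace.csv --out results/episode.png
```

The visualization draws one circle per decision point on an hour × weekday
grid — colour is the episode's desirability quantile, a black left half
marks a notification, a black right half marks a run.

## Layout

```
src/jitaisim/
  context.py     # ContextVector, factorized density fitting, likelihood ratio
  behavior.py    # cognitive dynamics, decision rule, weekly episodic env
  agents.py      # observation encoding, policy network, REINFORCE, baselines
  experiment.py  # multi-agent training runs, sliding windows, episode plots
  synth.py       # synthetic activity-log and weather-stream generators
  cli.py         # click CLI (console script `jitaisim`)
docs/methods.md  # model assumptions, defaults, calibration, limitations
```
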