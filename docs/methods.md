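# Methods

`jitaisim` couples three pieces: a data-driven model of how context favours
a target health activity, a stochastic simulator of a user who responds to
mobile notifications, and a budget-restricted policy-gradient agent that
learns when to send them.  This note records the model, the defaults, the
numerical choices, and what the synthetic data can and cannot show.

## The behavioral model

The simulated user is a dynamic Bayesian network over five variables per
hour *t*: notification `N_t` (binary, the agent's action), memory
accessibility `M_t ∈ (0,1]`, urge `U_t ∈ [0,1]`, context `C_t` (hour,
weekday, temperature, weather/wind/humidity categories) and the activity
decision `A_t` (binary).  The latent transitions are deterministic
(point-mass conditionals):

* `M_t = 1` if `N_t = 1`, else `σ · M_{t-1}` — a notification makes the
  activity maximally accessible in memory, after which accessibility decays
  geometrically (`σ = 0.8` per hour by default);
* `U_t = 0` if `A_{t-1} = 1`, else `min(1, U_{t-1} + μ)` — performing the
  activity resets the urge, which then recovers linearly (`μ = 0.05` per
  hour by default).

The decision couples the latent state with the observable context through a
likelihood ratio ("context desirability"):

    P(A_t = 1) = clamp( LR(C_t) · U_t · M_t , 0, 1 ),
    LR(C) = P(C | A = 1) / P(C).

Because the latent transitions are point masses, marginalizing over
`(M_t, U_t)` collapses to this single product; `decision_probability` is
tested against a brute-force grid enumeration of that marginalization.
The product form `P(A|U,M) = U · M` is the simplest monotone,
unit-interval-closed coupling that vanishes when either determinant is
absent; it is isolated in one swappable function
(`behavior.base_action_probability`).

## Context distributions

Both `P(C)` (from an hourly weather stream) and `P(C | A=1)` (from an
activity log) use the same factorization, fitted by maximum likelihood:

* weekday: categorical with 7 levels, treated as independent of the other
  features;
* `(weather, wind, humidity)`: categorical over observed combinations;
* `(hour, temperature)`: one bivariate Gaussian per discrete combination.

Numerical guards: every MLE covariance gets `+1e-6·I`; combinations with
fewer than 3 records fall back to the pooled Gaussian; densities are
floored at `1e-12` so the ratio never divides by zero; the ratio is capped
at 100 (the decision probability is clamped to 1 anyway, so the cap only
keeps intermediates finite).  Hour is modelled as a plain real, not a
circular variable: decision hours lie in 8:00–20:00, far from the
midnight wrap.  A context whose category level both models have never seen
gets ratio 1 (uninformative) rather than an arbitrary extreme.

## The episodic environment

An episode is one week.  The agent decides at every hour from 8:00 to
20:00 (13 decisions/day, 91/week); a run within the hour earns reward 1.0;
at most 14 notifications may be delivered per episode.  Episodes start at
0:00 of a random date in the weather stream; the stream supplies the
context (and hence the precomputed desirability) at every hour.

Hour bookkeeping convention: the state stored at a decision point holds the
previous hour's `(M, U)`, and the step applies the current hour's
transition.  Overnight (20:00 → 8:00) the simulator applies one
(decay, growth, no-decision) update per skipped hour — 11 of them — and the
8:00 step itself is the twelfth, so `σ` and `μ` keep their per-hour meaning.
At reset the initial state `(M, U) = (0.5, 0.5)` is defined at midnight and
advanced through 8 hourly updates, so memory at the first decision point is
`0.5 · σ^8`.  A run at 20:00 resets the urge at the next decision step (the
overnight updates are growth-only); runs can only occur at decision points.

## Agents

**REINFORCE with baseline.**  The policy is a feed-forward network (one
tanh hidden layer of 64 units, softmax over send/no-send) written directly
in numpy; its hand-derived gradient is pinned by a central-finite-difference
test at 1e-5.  After each episode the policy takes one plain gradient-ascent
step on `Σ_t log π(a_t|o_t) · (G_t − Ḡ_t)` with learning rate `α = 0.001`
and discount `γ = 1`; the baseline `Ḡ_t` is the per-step-position mean of
the returns over the past 50 episodes (ring buffer).  The output bias is
initialized so the initial send probability equals the budget rate
14/91 ≈ 0.15: a fresh policy then starts in the budget-feasible regime
instead of spending its budget in the first two days, which removes a long
unproductive clipping phase at the start of training.

**Budget restriction modes.**  R: once the budget is spent the agent forces
no-send; forced steps carry no log-probability and are excluded from the
gradient (this also avoids `log 0`).  C: the agent samples freely and the
environment suppresses over-budget deliveries.  B: unrestricted until a
switch episode, then environment-side suppression.

**Observation.**  One-hot weekday/weather/wind/humidity, hour/24,
temperature/30, `log10 LR(C_t)/2`, remaining-budget fraction,
hours-since-last-run (capped at 48 h), and episode progress (step/91).  The
desirability feature is the value of the system's *own* fitted context
models at the current context — knowledge the notification system holds by
construction, not a peek at the user.  Budget, progress and run-recency are
what make the two canonical strategies representable: spreading a weekly
budget requires knowing both how much budget and how much episode remain
(episodes start on a random weekday, so the weekday one-hot does not encode
episode position), and "don't notify right after a run" requires run
recency.  The user's latent `M` and `U` are never observed.

**Rule-based baselines.**  random-week: 14 of the 91 decision steps,
uniform without replacement per episode; random-day: 2 of the 13 daily
steps, uniform without replacement per day; fixed: 12:00 and 16:00 every
day.

## Synthetic data

The generator emulates the *structure* of two real data sources — an
activity log with weather metadata and an hourly national weather archive —
without reproducing any real records.

* **Weather stream**: the discrete combination follows a sticky first-order
  chain (stay probability 0.9, otherwise redraw from the prior combo
  distribution, which is therefore the stationary law; regimes last ~10 h);
  temperature is drawn from the combo's bivariate (hour, temperature)
  Gaussian conditioned on the calendar hour, giving a diurnal cycle.
  Weekdays come from the calendar, so the prior weekday distribution is
  uniform up to stream-length effects.
* **Activity log**: contexts are sampled from a shifted conditional law —
  weekends up-weighted (Sat 1.6×, Sun 1.5×), mild/calm weather preferred
  (clear 2.5×, rain 0.25×, snow 0.1×, calm 1.5×, strong wind 0.3×),
  temperature +2.5 °C, and the hour of day concentrated on an after-work
  evening peak (mean 18.5, sd 4.0 h, versus the prior's uniform hours).

Default scale: 10,000 activity records and 2 years of hourly weather —
small enough to regenerate in seconds, large enough that every well-
populated per-combo Gaussian fit is stable.

The shift was calibrated once against explicit qualitative targets drawn
from the phenomena the simulator must reproduce, and then frozen: typical
decision-hour desirability of order 0.1–2 with an upper tail of 3–10
(afternoon medians by weather: clear ≈ 3, cloudy ≈ 1.3, rain ≈ 0.2,
snow ≈ 0.03, so day quality varies materially); notification conversion
well below 1 (a fixed schedule converts ≈ 35–45 % of its sends, so context
modulates each notification rather than saturating it); and runs without
any notification are rare (≈ 0.2/week), so reward is genuinely
notification-driven.

What the synthetic world does *not* emulate: seasonal and annual cycles,
weekday-dependent hour profiles (the fitted model class assumes weekday
independence, so the generator plants none), user heterogeneity, and any
real climatology.  A consequence worth stating plainly: because the
within-day desirability profile is the same shape every day under this
model class, well-spaced fixed schedules are strong competitors here —
passing or failing a comparison against them says how well the learner
times and spaces its budget in *this* world, not how the method would fare
on the real datasets.

## Experiments

Each repetition seeds one `SeedSequence`; the environment seed is shared by
every agent in that repetition (same start dates, same user-decision
randomness), while each agent draws its own policy/initialization stream.
Learning curves report trailing means over 500-episode windows; window
means are recomputable exactly from the per-episode CSV, and a sidecar JSON
records the full configuration and seeds.  The episode visualization draws
one circle per decision point on an hour × weekday grid, colours it by the
episode's desirability quantile (5 diverging classes; a degenerate episode
collapses to the middle class), and marks notifications (left half) and
runs (right half).

Problem sizes used by the acceptance runs (chosen as desk-scale defaults):
comparison experiments run 3 repetitions at a few thousand to a few tens of
thousands of weekly episodes per agent; statistical claims are made at the
level of seed orderings and window means, never single episodes.

## Known limitations

* One simulated user; no population variation or transfer.
* Single-Gaussian hour profiles cannot express multi-modal daily activity
  patterns (e.g. separate lunchtime and evening peaks).
* REINFORCE with one update per episode at `α = 0.001` learns slowly; tens
  of thousands of episodes are needed before the context-aware policy
  separates from schedule baselines.
* The urge cap (`μ = 0.05`/h ⇒ ≈ 8.4 urge-units/week) bounds attainable
  weekly reward for any policy; comparisons between good policies compress
  toward that ceiling.
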