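"""Synthetic activity-log and hourly-weather generators.

The simulator's context models are normally fitted from two large real
datasets: a log of performed runs with the weather at each run, and an
hourly national weather archive.  This module generates structurally
faithful surrogates for both so the whole pipeline runs from scratch:

* the **weather stream** is an hourly series whose discrete weather
  combination ``(weather, wind, humidity)`` follows a first-order sticky
  categorical chain (stationary distribution equal to the configured prior
  combo probabilities) and whose temperature is drawn from the combo's
  bivariate (hour, temperature) Gaussian conditioned on the hour of day;
* the **activity log** samples contexts from a shifted, activity-conditional
  distribution — reweighted weekdays, reweighted combos, offset Gaussian
  means and rescaled covariances — so that the likelihood ratio
  ``P(C|A=1)/P(C)`` carries real signal.

The default world is deliberately modest in scale (tens of thousands of
rows) while keeping every per-combo Gaussian fit stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .context import CSV_COLUMNS, WEEKDAYS

#: Calendar anchor for generated timestamps (a Monday).
STREAM_EPOCH = np.datetime64("2015-01-05T00:00")


def _product_probs(weather_p, wind_p, humidity_p):
    keys, probs = [], []
    for (w, pw) in weather_p.items():
        for (wi, pwi) in wind_p.items():
            for (h, ph) in humidity_p.items():
                keys.append((w, wi, h))
                probs.append(pw * pwi * ph)
    p = np.asarray(probs)
    return keys, p / p.sum()


@dataclass
class DistributionShift:
    """How the activity-conditional distribution differs from the prior.

    ``weekday_weights`` and ``combo_weights`` multiply the prior
    probabilities (then renormalize); the mean offsets move every combo's
    (hour, temperature) Gaussian; ``cov_scale`` shrinks or inflates its
    covariance.  An all-default shift is the identity: the activity log then
    has the same distribution as the prior and the fitted ratio is ~1.
    """

    weekday_weights: dict[str, float] = field(default_factory=dict)
    combo_weights: dict[tuple[str, str, str], float] = field(default_factory=dict)
    hour_mean_offset: float = 0.0
    temp_mean_offset: float = 0.0
    cov_scale: float = 1.0
    hour_mean_target: float | None = None   # overrides the offset if set
    hour_std_target: float | None = None


@dataclass
class SyntheticWorldParams:
    """Ground-truth world: prior context distribution plus the activity shift.

    Defaults sketch a temperate maritime climate with four weather types and
    an activity population that prefers weekends, late afternoons, mild
    weather and calm wind.
    """

    weather_probs: dict[str, float] = field(default_factory=lambda: {
        "clear": 0.30, "cloudy": 0.40, "rain": 0.25, "snow": 0.05})
    wind_probs: dict[str, float] = field(default_factory=lambda: {
        "calm": 0.40, "moderate": 0.40, "strong": 0.20})
    humidity_probs: dict[str, float] = field(default_factory=lambda: {
        "low": 0.30, "moderate": 0.50, "high": 0.20})
    #: mean daily temperature per weather type (deg C)
    temp_means: dict[str, float] = field(default_factory=lambda: {
        "clear": 14.0, "cloudy": 10.0, "rain": 8.0, "snow": -1.0})
    temp_std: float = 5.0
    #: within-day temperature swing amplitude (deg C), peak mid-afternoon
    diurnal_amplitude: float = 3.0
    #: probability the next hour keeps the current weather combo
    persistence: float = 0.9
    shift: DistributionShift = field(default_factory=lambda: DistributionShift(
        weekday_weights={"Mon": 0.8, "Tue": 0.8, "Wed": 0.8, "Thu": 0.8,
                         "Fri": 0.9, "Sat": 1.6, "Sun": 1.5},
        combo_weights={},
        temp_mean_offset=2.5,
        cov_scale=0.8,
        hour_mean_target=18.5,
        hour_std_target=4.0,
    ))
    #: multiplicative preference for weather/wind levels among runs
    shift_weather_weights: dict[str, float] = field(default_factory=lambda: {
        "clear": 2.5, "cloudy": 1.0, "rain": 0.25, "snow": 0.1})
    shift_wind_weights: dict[str, float] = field(default_factory=lambda: {
        "calm": 1.5, "moderate": 1.0, "strong": 0.3})

    def combos(self):
        return _product_probs(self.weather_probs, self.wind_probs,
                              self.humidity_probs)

    # -- per-combo Gaussians ------------------------------------------------

    def prior_gaussian(self, combo):
        """Ground-truth prior (hour, temperature) Gaussian for one combo.

        Hour is ~uniform over the day in an hourly stream; its Gaussian
        projection has mean 11.5 and variance (24^2 - 1)/12.  Temperature
        couples to hour through the diurnal cycle, giving the positive
        off-diagonal term.
        """
        weather = combo[0]
        hour_mean, hour_var = 11.5, (24.0 ** 2 - 1.0) / 12.0
        # linearized diurnal coupling: cov(h, T) from T = m + a*sin(...) ~ slope*h
        slope = self.diurnal_amplitude * 2.0 * np.pi / 24.0 * 0.6
        cov_ht = slope * hour_var * 0.5
        temp_var = self.temp_std ** 2 + 0.5 * self.diurnal_amplitude ** 2
        mean = np.array([hour_mean, self.temp_means[weather]])
        cov = np.array([[hour_var, cov_ht], [cov_ht, temp_var]])
        return mean, cov

    def conditional_gaussian(self, combo):
        """Activity-conditional (hour, temperature) Gaussian for one combo."""
        mean, cov = self.prior_gaussian(combo)
        s = self.shift
        mean = mean + np.array([s.hour_mean_offset, s.temp_mean_offset])
        cov = cov * s.cov_scale
        if s.hour_mean_target is not None:
            mean[0] = s.hour_mean_target
        if s.hour_std_target is not None:
            ratio = s.hour_std_target ** 2 / cov[0, 0]
            cov = cov.copy()
            cov[0, 1] *= np.sqrt(ratio)
            cov[1, 0] = cov[0, 1]
            cov[0, 0] = s.hour_std_target ** 2
        return mean, cov

    def conditional_weekday_probs(self) -> dict[str, float]:
        w = np.array([self.shift.weekday_weights.get(d, 1.0) for d in WEEKDAYS])
        w = w / 7.0
        w = w / w.sum()
        return dict(zip(WEEKDAYS, w))

    def conditional_combo_probs(self):
        keys, p = self.combos()
        weights = np.array([
            self.shift.combo_weights.get(
                k, self.shift_weather_weights.get(k[0], 1.0)
                * self.shift_wind_weights.get(k[1], 1.0))
            for k in keys])
        p = p * weights
        return keys, p / p.sum()


def _weekday_of(ts: np.datetime64) -> str:
    day_index = (ts.astype("datetime64[D]").astype(int) + 3) % 7  # epoch was a Thu
    return WEEKDAYS[day_index]


def generate_weather_stream(params: SyntheticWorldParams, n_hours: int,
                            seed: int | np.random.Generator) -> pd.DataFrame:
    """Generate an hourly weather stream of ``n_hours`` consecutive rows.

    The combo follows a sticky chain: keep the current combo with
    probability ``persistence``, otherwise redraw from the prior combo
    distribution — which is therefore also the chain's stationary law.
    """
    rng = np.random.default_rng(seed)
    keys, probs = params.combos()
    combo_idx = np.empty(n_hours, dtype=int)
    combo_idx[0] = rng.choice(len(keys), p=probs)
    stay = rng.random(n_hours) < params.persistence
    redraw = rng.choice(len(keys), p=probs, size=n_hours)
    for t in range(1, n_hours):
        combo_idx[t] = combo_idx[t - 1] if stay[t] else redraw[t]

    hours = np.arange(n_hours) % 24
    timestamps = STREAM_EPOCH + np.arange(n_hours).astype("timedelta64[h]")
    weekdays = [WEEKDAYS[int(d)] for d in
                ((timestamps.astype("datetime64[D]").astype(int) + 3) % 7)]

    temps = np.empty(n_hours)
    for t in range(n_hours):
        mean, cov = params.prior_gaussian(keys[combo_idx[t]])
        h = hours[t]
        # conditional T | hour from the combo's bivariate Gaussian
        mu_t = mean[1] + cov[0, 1] / cov[0, 0] * (h - mean[0])
        var_t = cov[1, 1] - cov[0, 1] ** 2 / cov[0, 0]
        temps[t] = rng.normal(mu_t, np.sqrt(var_t))

    return pd.DataFrame({
        "timestamp": np.datetime_as_string(timestamps, unit="m"),
        "hour": hours,
        "weekday": weekdays,
        "temperature": np.round(temps, 2),
        "weather": [keys[i][0] for i in combo_idx],
        "wind": [keys[i][1] for i in combo_idx],
        "humidity": [keys[i][2] for i in combo_idx],
    })[CSV_COLUMNS]


def generate_activity_log(params: SyntheticWorldParams, n_records: int,
                          seed: int | np.random.Generator) -> pd.DataFrame:
    """Sample ``n_records`` performed-activity contexts from the shifted law."""
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    rng = np.random.default_rng(seed)
    wd_probs = params.conditional_weekday_probs()
    weekdays = rng.choice(WEEKDAYS, size=n_records,
                          p=[wd_probs[d] for d in WEEKDAYS])
    keys, cprobs = params.conditional_combo_probs()
    combo_idx = rng.choice(len(keys), size=n_records, p=cprobs)

    hours = np.empty(n_records)
    temps = np.empty(n_records)
    for i, ci in enumerate(combo_idx):
        mean, cov = params.conditional_gaussian(keys[ci])
        x = rng.multivariate_normal(mean, cov)
        hours[i] = np.clip(x[0], 0.0, 23.99)
        temps[i] = x[1]

    # timestamps consistent with the sampled weekday and hour
    week = rng.integers(0, 52, size=n_records)
    day_offset = np.array([WEEKDAYS.index(d) for d in weekdays])
    ts = (STREAM_EPOCH
          + ((week * 7 + day_offset) * 24).astype("timedelta64[h]")
          + np.floor(hours * 60).astype("timedelta64[m]"))

    df = pd.DataFrame({
        "timestamp": np.datetime_as_string(ts, unit="m"),
        "hour": np.round(hours, 2),
        "weekday": weekdays,
        "temperature": np.round(temps, 2),
        "weather": [keys[i][0] for i in combo_idx],
        "wind": [keys[i][1] for i in combo_idx],
        "humidity": [keys[i][2] for i in combo_idx],
    })[CSV_COLUMNS]
    return df.sort_values("timestamp", kind="stable").reset_index(drop=True)


def generate_world(params: SyntheticWorldParams | None = None,
                   n_activity: int = 10_000, n_hours: int = 17_520,
                   seed: int = 0):
    """Convenience: (activity_log, weather_stream) at the default desk scale.

    Two years of hourly weather and 10,000 activity records keep every
    per-combo Gaussian fit stable while remaining fast to fit.
    """
    params = params or SyntheticWorldParams()
    ss = np.random.SeedSequence(seed)
    s_act, s_wx = ss.spawn(2)
    log = generate_activity_log(params, n_activity, np.random.default_rng(s_act))
    stream = generate_weather_stream(params, n_hours, np.random.default_rng(s_wx))
    return log, stream
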