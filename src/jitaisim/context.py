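"""Factorized context distributions and the context-desirability likelihood ratio.

The simulator scores how favourable a momentary context ``C`` (time of day,
weekday, weather) is for the target activity ``A`` through the ratio
``P(C | A=1) / P(C)``.  Both densities share one factorized form fitted from
logs by maximum likelihood:

* a categorical distribution over weekday (conditionally independent of the
  other features),
* a categorical distribution over the discrete weather combination
  ``(weather, wind, humidity)``,
* a bivariate Gaussian over the continuous pair ``(hour, temperature)``
  fitted separately within each discrete combination.

``P(C | A=1)`` is fitted from an activity log (one row per performed
activity); ``P(C)`` from an hourly weather stream.  Densities are mixed
probability-mass/density values and are only ever used inside ratios.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import multivariate_normal

WEEKDAYS = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")

#: Floor for the density of a context unseen at fit time; keeps the ratio finite.
DENSITY_FLOOR = 1e-12
#: Cap applied to the likelihood ratio before it multiplies a probability.
RATIO_MAX = 100.0
#: Tikhonov term added to every MLE covariance.
COV_RIDGE = 1e-6
#: Minimum records in a discrete combination before it gets its own Gaussian.
MIN_COMBO_RECORDS = 3

CSV_COLUMNS = ["timestamp", "hour", "weekday", "temperature",
               "weather", "wind", "humidity"]


@dataclass(frozen=True)
class ContextVector:
    """One decision point's observable context."""

    hour: float
    weekday: str
    temperature: float
    weather: str
    wind: str
    humidity: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.hour < 24.0:
            raise ValueError(f"hour must lie in [0, 24), got {self.hour}")
        if self.weekday not in WEEKDAYS:
            raise ValueError(f"unknown weekday {self.weekday!r}")

    @property
    def combo(self) -> tuple[str, str, str]:
        return (self.weather, self.wind, self.humidity)


@dataclass
class ComboGaussian:
    """MLE bivariate Gaussian over (hour, temperature) within one combo."""

    mean: np.ndarray          # shape (2,)
    cov: np.ndarray           # shape (2, 2), symmetric positive-definite

    def pdf(self, hour: float, temperature: float) -> float:
        return float(multivariate_normal(self.mean, self.cov).pdf([hour, temperature]))


@dataclass
class ContextDistributionModel:
    """Fitted factorized density for P(C) or P(C | A=1)."""

    level_sets: dict[str, list[str]]
    weekday_probs: dict[str, float]
    combo_probs: dict[tuple[str, str, str], float]
    combo_gaussians: dict[tuple[str, str, str], ComboGaussian]
    pooled_gaussian: ComboGaussian
    density_floor: float = DENSITY_FLOOR
    _mvn_cache: dict = field(default_factory=dict, repr=False)

    def _frozen(self, combo):
        try:
            return self._mvn_cache[combo]
        except KeyError:
            g = self.combo_gaussians.get(combo, self.pooled_gaussian)
            fr = multivariate_normal(g.mean, g.cov)
            self._mvn_cache[combo] = fr
            return fr

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "level_sets": self.level_sets,
            "weekday_probs": self.weekday_probs,
            "density_floor": self.density_floor,
            "pooled_gaussian": {
                "mean": self.pooled_gaussian.mean.tolist(),
                "cov": self.pooled_gaussian.cov.tolist(),
            },
            "combos": [
                {
                    "weather": w, "wind": wi, "humidity": h,
                    "prob": p,
                    "mean": self.combo_gaussians[(w, wi, h)].mean.tolist()
                    if (w, wi, h) in self.combo_gaussians else None,
                    "cov": self.combo_gaussians[(w, wi, h)].cov.tolist()
                    if (w, wi, h) in self.combo_gaussians else None,
                }
                for (w, wi, h), p in sorted(self.combo_probs.items())
            ],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ContextDistributionModel":
        d = json.loads(text)
        pooled = ComboGaussian(np.asarray(d["pooled_gaussian"]["mean"], float),
                               np.asarray(d["pooled_gaussian"]["cov"], float))
        combo_probs, combo_gaussians = {}, {}
        for c in d["combos"]:
            key = (c["weather"], c["wind"], c["humidity"])
            combo_probs[key] = c["prob"]
            if c["mean"] is not None:
                combo_gaussians[key] = ComboGaussian(np.asarray(c["mean"], float),
                                                     np.asarray(c["cov"], float))
        return cls(level_sets={k: list(v) for k, v in d["level_sets"].items()},
                   weekday_probs=d["weekday_probs"],
                   combo_probs=combo_probs,
                   combo_gaussians=combo_gaussians,
                   pooled_gaussian=pooled,
                   density_floor=d.get("density_floor", DENSITY_FLOOR))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "ContextDistributionModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def _mle_gaussian(hours: np.ndarray, temps: np.ndarray) -> ComboGaussian:
    x = np.column_stack([hours, temps]).astype(float)
    mean = x.mean(axis=0)
    centered = x - mean
    cov = centered.T @ centered / len(x)          # MLE (biased) covariance
    cov = cov + COV_RIDGE * np.eye(2)
    return ComboGaussian(mean=mean, cov=cov)


def fit_context_distribution(records) -> ContextDistributionModel:
    """Fit the factorized context model by maximum likelihood.

    Parameters
    ----------
    records
        Either a list of :class:`ContextVector` or a DataFrame with columns
        ``hour, weekday, temperature, weather, wind, humidity``.

    Weekday and combo probabilities are empirical frequencies; each combo
    with at least ``MIN_COMBO_RECORDS`` rows gets its own MLE Gaussian over
    (hour, temperature), smaller combos fall back to the pooled Gaussian.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        if not records:
            raise ValueError("cannot fit a context model on an empty record set")
        df = pd.DataFrame(
            {
                "hour": [r.hour for r in records],
                "weekday": [r.weekday for r in records],
                "temperature": [r.temperature for r in records],
                "weather": [r.weather for r in records],
                "wind": [r.wind for r in records],
                "humidity": [r.humidity for r in records],
            }
        )
    if len(df) == 0:
        raise ValueError("cannot fit a context model on an empty record set")

    n = len(df)
    weekday_counts = df["weekday"].value_counts()
    weekday_probs = {d: float(weekday_counts.get(d, 0)) / n for d in WEEKDAYS}

    level_sets = {
        "weekday": list(WEEKDAYS),
        "weather": sorted(df["weather"].unique()),
        "wind": sorted(df["wind"].unique()),
        "humidity": sorted(df["humidity"].unique()),
    }

    pooled = _mle_gaussian(df["hour"].to_numpy(), df["temperature"].to_numpy())

    combo_probs: dict[tuple[str, str, str], float] = {}
    combo_gaussians: dict[tuple[str, str, str], ComboGaussian] = {}
    for combo, grp in df.groupby(["weather", "wind", "humidity"], sort=True):
        combo_probs[combo] = len(grp) / n
        if len(grp) >= MIN_COMBO_RECORDS:
            combo_gaussians[combo] = _mle_gaussian(
                grp["hour"].to_numpy(), grp["temperature"].to_numpy())

    return ContextDistributionModel(
        level_sets=level_sets,
        weekday_probs=weekday_probs,
        combo_probs=combo_probs,
        combo_gaussians=combo_gaussians,
        pooled_gaussian=pooled,
    )


def context_density(model: ContextDistributionModel, c: ContextVector) -> float:
    """Mixed mass/density of one context under the factorized model.

    Returns ``P(weekday) * P(combo) * N(hour, temperature | combo)``, floored
    at ``model.density_floor`` so downstream ratios never divide by zero.
    """
    w = model.weekday_probs.get(c.weekday, 0.0)
    p_combo = model.combo_probs.get(c.combo, 0.0)
    if w <= 0.0 or p_combo <= 0.0:
        return model.density_floor
    dens = w * p_combo * float(model._frozen(c.combo).pdf([c.hour, c.temperature]))
    return max(dens, model.density_floor)


def likelihood_ratio(cond: ContextDistributionModel,
                     prior: ContextDistributionModel,
                     c: ContextVector,
                     ratio_max: float = RATIO_MAX) -> float:
    """Context desirability ``P(C|A=1) / P(C)``, clipped to ``[0, ratio_max]``.

    When both densities sit at their floors (the context is unseen by both
    models) the ratio is uninformative and 1 is returned.
    """
    num = context_density(cond, c)
    den = context_density(prior, c)
    if num <= cond.density_floor and den <= prior.density_floor:
        return 1.0
    return float(np.clip(num / den, 0.0, ratio_max))


def likelihood_ratio_profile(cond: ContextDistributionModel,
                             prior: ContextDistributionModel,
                             stream: pd.DataFrame,
                             ratio_max: float = RATIO_MAX) -> np.ndarray:
    """Vectorized :func:`likelihood_ratio` over every row of a weather stream.

    Used by the environment to precompute desirability once per stream.
    """
    n = len(stream)
    out = np.empty(n)
    num = np.empty(n)
    den = np.empty(n)
    for model, buf in ((cond, num), (prior, den)):
        wmap = model.weekday_probs
        w = stream["weekday"].map(lambda d: wmap.get(d, 0.0)).to_numpy(float)
        buf[:] = 0.0
        xy = stream[["hour", "temperature"]].to_numpy(float)
        for combo, idx in stream.groupby(["weather", "wind", "humidity"]).groups.items():
            p_combo = model.combo_probs.get(combo, 0.0)
            if p_combo <= 0.0:
                continue
            loc = stream.index.get_indexer(idx)
            buf[loc] = p_combo * model._frozen(combo).pdf(xy[loc])
        buf *= w
        np.maximum(buf, model.density_floor, out=buf)
    at_floor = (num <= cond.density_floor) & (den <= prior.density_floor)
    out = np.clip(num / den, 0.0, ratio_max)
    out[at_floor] = 1.0
    return out


def read_context_csv(path) -> pd.DataFrame:
    """Read an activity-log or weather-stream CSV (shared column dialect)."""
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"context CSV missing columns: {sorted(missing)}")
    return df
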