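"""Synthetic child-level microdata generator.

Emulates the statistical structure of the survey microdata the analysis
assumes — children aged 6–23 months with a socioeconomic decile, an
altitude, an (unadjusted and altitude-adjusted) hemoglobin value, and a
fortified-infant-cereal consumption duration — so the estimation stages and
the microsimulation oracles run without any external data.

Consumption is linked to hemoglobin only through the dose-response model:
each child's Hb is drawn from a normal centred on its decile mean plus the
(mean-centred) effect of its own consumption duration. Centring keeps the
pooled stratum mean at the configured decile mean, so parameter-recovery
experiments are clean. An optional wealth-confounding switch makes the
probability of consuming increase with the decile, emulating the real-data
caveat that wealth also shapes diet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .hemoglobin import AltitudeTable, EffectModel, fic_effect
from .inputs import MAX_DURATION, DEFAULT_TERTILE_MAP, ValidationError

# default duration bands among consumers (never-consumers handled separately):
# 17% < 3 months, 21% at 3-5, 25% at 6-11, 11% at 12+, uniform within bands
_DEFAULT_BANDS = {(1, 2): 0.17, (3, 5): 0.21, (6, 11): 0.25, (12, MAX_DURATION): 0.11}


def _band_pmf(consumer_fraction: float) -> dict[int, float]:
    pmf = {0: 1.0 - consumer_fraction}
    total = sum(_DEFAULT_BANDS.values())
    for (lo, hi), mass in _DEFAULT_BANDS.items():
        scaled = mass / total * consumer_fraction
        for d in range(lo, hi + 1):
            pmf[d] = pmf.get(d, 0.0) + scaled / (hi - lo + 1)
    return pmf


@dataclass(frozen=True)
class SurveyConfig:
    """Configuration of the synthetic survey generator."""

    n_children: int = 1000
    seed: int = 0
    decile_weights: tuple[float, ...] = (0.1,) * 10
    decile_hb_means: tuple[float, ...] = (10.4, 10.4, 10.5, 10.6, 10.8, 10.9, 11.1, 11.1, 11.2, 11.2)
    hb_sd: float = 1.4
    consumer_fraction: float = 0.74
    duration_pmf: dict[int, float] | None = None
    age_range_months: tuple[int, int] = (6, 23)
    # (upper altitude bound m, probability); Indonesia is predominantly lowland
    altitude_bands: tuple[tuple[float, float], ...] = ((500.0, 0.85), (1000.0, 0.10), (2000.0, 0.05))
    effect_model: EffectModel = field(default_factory=EffectModel)
    servings_per_day: float = 1.0
    wealth_confounding: float = 0.0  # slope of consumption probability in decile

    def __post_init__(self):
        if self.n_children < 1:
            raise ValidationError("n_children must be >= 1")
        if len(self.decile_weights) != 10 or abs(sum(self.decile_weights) - 1.0) > 1e-9:
            raise ValidationError("decile_weights must be 10 fractions summing to 1")
        if len(self.decile_hb_means) != 10:
            raise ValidationError("decile_hb_means must have 10 entries")
        if not 0.0 <= self.consumer_fraction <= 1.0:
            raise ValidationError("consumer_fraction outside [0, 1]")
        if self.hb_sd <= 0:
            raise ValidationError("hb_sd must be positive")
        if self.duration_pmf is not None and abs(sum(self.duration_pmf.values()) - 1.0) > 1e-9:
            raise ValidationError("duration_pmf must sum to 1")
        if abs(sum(p for _, p in self.altitude_bands) - 1.0) > 1e-9:
            raise ValidationError("altitude band probabilities must sum to 1")

    def effective_duration_pmf(self) -> dict[int, float]:
        if self.duration_pmf is not None:
            return dict(self.duration_pmf)
        return _band_pmf(self.consumer_fraction)


COLUMNS = ("id", "age_months", "decile", "tertile", "altitude_m",
           "hb_gdl", "hb_adjusted_gdl", "fic_duration_months", "servings_per_day")


def generate_survey(config: SurveyConfig) -> pd.DataFrame:
    """Generate a reproducible child-level survey as a DataFrame.

    Children are assigned a decile, an age, an altitude band, a consumption
    duration, and an altitude-adjusted Hb drawn from
    normal(decile mean + effect(duration) - mean effect, hb_sd); the
    unadjusted Hb adds the altitude decrement back.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_children
    table = AltitudeTable()

    deciles = rng.choice(np.arange(1, 11), size=n, p=np.asarray(config.decile_weights))
    ages = rng.integers(config.age_range_months[0], config.age_range_months[1] + 1, size=n)

    pmf = config.effective_duration_pmf()
    durations_support = np.array(sorted(pmf))
    base_probs = np.array([pmf[d] for d in durations_support], dtype=float)
    if config.wealth_confounding:
        # tilt the consumer/non-consumer split linearly in decile, keeping the
        # consumer-conditional duration distribution fixed
        c0 = 1.0 - base_probs[durations_support == 0].sum()
        cond = np.where(durations_support > 0, base_probs, 0.0)
        cond = cond / cond.sum() if c0 > 0 else cond
        durations = np.empty(n, dtype=int)
        for d in range(1, 11):
            mask = deciles == d
            c_d = np.clip(c0 + config.wealth_confounding * (d - 5.5), 0.0, 1.0)
            probs = cond * c_d
            probs[durations_support == 0] = 1.0 - c_d
            durations[mask] = rng.choice(durations_support, size=mask.sum(), p=probs)
    else:
        durations = rng.choice(durations_support, size=n, p=base_probs)

    effects = np.array([
        fic_effect(float(d), config.effect_model, config.servings_per_day)
        for d in durations_support
    ])
    mean_effect = float(np.dot(base_probs, effects))
    effect_of = dict(zip(durations_support.tolist(), effects.tolist()))

    bounds = np.array([b for b, _ in config.altitude_bands])
    probs_alt = np.array([p for _, p in config.altitude_bands])
    band_idx = rng.choice(len(bounds), size=n, p=probs_alt)
    lows = np.concatenate([[0.0], bounds[:-1]])
    altitudes = rng.uniform(lows[band_idx], bounds[band_idx])

    mu = np.array([config.decile_hb_means[d - 1] for d in deciles])
    shift = np.array([effect_of[int(d)] for d in durations]) - mean_effect
    hb_adjusted = rng.normal(mu + shift, config.hb_sd)
    hb_adjusted = np.maximum(hb_adjusted, 0.1)
    decrements = np.array([table.decrement(a) for a in altitudes])
    hb_raw = hb_adjusted + decrements

    return pd.DataFrame({
        "id": np.arange(n),
        "age_months": ages,
        "decile": deciles,
        "tertile": np.array([DEFAULT_TERTILE_MAP[int(d)] for d in deciles]),
        "altitude_m": altitudes,
        "hb_gdl": hb_raw,
        "hb_adjusted_gdl": hb_adjusted,
        "fic_duration_months": durations,
        "servings_per_day": np.full(n, config.servings_per_day),
    })


def summarize_by_duration(survey: pd.DataFrame, bins: Sequence[int] | None = None) -> pd.DataFrame:
    """Mean Hb per consumption-duration bin, with counts.

    Empty bins are absent from the result rather than reported as zero.
    """
    if survey.empty:
        raise ValidationError("survey is empty")
    col = "hb_adjusted_gdl" if "hb_adjusted_gdl" in survey.columns else "hb_gdl"
    if bins is None:
        grouped = survey.groupby("fic_duration_months")[col]
    else:
        labels = pd.cut(survey["fic_duration_months"], bins=list(bins), right=False)
        grouped = survey.groupby(labels, observed=True)[col]
    out = grouped.agg(mean_hb="mean", sd_hb="std", n="size")
    return out[out["n"] > 0]
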