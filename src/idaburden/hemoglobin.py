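"""Hemoglobin distribution machinery.

Covers altitude adjustment of measured Hb, WHO-style anemia severity
classification, prevalence computed from a (normal or empirical) Hb
distribution, decile-mean estimation from child-level microdata, the lagged
consumption→Hb dose-response of fortified infant cereals (FIC), and the
counterfactual shift that removes (or adds) the FIC effect at the population
level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .inputs import ConsumptionProfile, ValidationError

Severity = Literal["none", "mild", "moderate", "severe"]
SEVERITIES: tuple[Severity, ...] = ("none", "mild", "moderate", "severe")


@dataclass(frozen=True)
class AnemiaPrevalence:
    """Population fractions by anemia severity; the four fractions sum to 1."""

    none: float
    mild: float
    moderate: float
    severe: float

    def __post_init__(self):
        vals = self.as_array()
        if np.any(vals < -1e-12) or np.any(vals > 1 + 1e-12):
            raise ValidationError(f"prevalence fractions outside [0, 1]: {vals}")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValidationError(f"prevalence fractions sum to {vals.sum()}, not 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.none, self.mild, self.moderate, self.severe])

    @property
    def any_anemia(self) -> float:
        return self.mild + self.moderate + self.severe


@dataclass(frozen=True)
class HbDistribution:
    """A hemoglobin distribution, normal by default or an empirical sample."""

    mean: float
    sd: float
    family: Literal["normal", "empirical"] = "normal"
    sample: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.family == "empirical":
            if not self.sample:
                raise ValidationError("empirical family requires a non-empty sample")
        elif self.sd <= 0:
            raise ValidationError("sd must be positive")


@dataclass(frozen=True)
class HbMixture:
    """A finite mixture of normal Hb components (weight, mean, sd)."""

    components: tuple[tuple[float, float, float], ...]

    def __post_init__(self):
        w = np.array([c[0] for c in self.components])
        if np.any(w < -1e-12) or abs(w.sum() - 1.0) > 1e-9:
            raise ValidationError("mixture weights must be non-negative and sum to 1")

    @property
    def mean(self) -> float:
        return float(sum(w * m for w, m, _ in self.components))

    @property
    def sd(self) -> float:
        mu = self.mean
        var = sum(w * (s * s + (m - mu) ** 2) for w, m, s in self.components)
        return float(np.sqrt(var))


# Altitude bands (meters above sea level -> g/dL subtracted from measured Hb),
# the WHO adjustment used when surveys report sea-level-equivalent anemia.
DEFAULT_ALTITUDE_TABLE: tuple[tuple[float, float], ...] = (
    (1000.0, 0.2),
    (1500.0, 0.5),
    (2000.0, 0.8),
    (2500.0, 1.3),
    (3000.0, 1.9),
    (3500.0, 2.7),
    (4000.0, 3.5),
    (4500.0, 4.5),
)


@dataclass(frozen=True)
class AltitudeTable:
    """Ordered (altitude breakpoint, Hb decrement) bands; zero below the first."""

    breakpoints: tuple[tuple[float, float], ...] = DEFAULT_ALTITUDE_TABLE

    def __post_init__(self):
        alts = [a for a, _ in self.breakpoints]
        decs = [d for _, d in self.breakpoints]
        if sorted(alts) != alts or sorted(decs) != decs:
            raise ValidationError("altitude breakpoints and decrements must be non-decreasing")

    def decrement(self, altitude_m: float) -> float:
        if altitude_m < 0:
            raise ValidationError("altitude must be >= 0")
        d = 0.0
        for alt, dec in self.breakpoints:
            if altitude_m >= alt:
                d = dec
        return d


def adjust_for_altitude(hb_gdl: float, altitude_m: float, table: AltitudeTable | None = None) -> float:
    """Altitude-adjusted hemoglobin: measured Hb minus the band decrement."""
    if hb_gdl <= 0:
        raise ValidationError("hb must be positive")
    table = table or AltitudeTable()
    return hb_gdl - table.decrement(altitude_m)


def classify_anemia(hb_gdl: float, cutoffs: Sequence[float] = (7.0, 10.0, 11.0)) -> Severity:
    """Severity of anemia for one altitude-adjusted Hb value.

    severe < c1 <= moderate < c2 <= mild < c3 <= none.
    """
    c1, c2, c3 = cutoffs
    if not c1 < c2 < c3:
        raise ValidationError(f"cutoffs must be strictly increasing, got {tuple(cutoffs)}")
    if hb_gdl < c1:
        return "severe"
    if hb_gdl < c2:
        return "moderate"
    if hb_gdl < c3:
        return "mild"
    return "none"


def _normal_band_probs(mean: float, sd: float, cutoffs: Sequence[float]) -> np.ndarray:
    c1, c2, c3 = cutoffs
    cdf = stats.norm.cdf([c1, c2, c3], loc=mean, scale=sd)
    return np.array([1.0 - cdf[2], cdf[2] - cdf[1], cdf[1] - cdf[0], cdf[0]])


def prevalence_from_distribution(
    dist: HbDistribution | HbMixture, cutoffs: Sequence[float] = (7.0, 10.0, 11.0)
) -> AnemiaPrevalence:
    """Anemia severity fractions implied by an Hb distribution.

    Normal distributions use exact normal band probabilities; mixtures sum
    them over components; empirical distributions count the sample.
    """
    c1, c2, c3 = cutoffs
    if not c1 < c2 < c3:
        raise ValidationError(f"cutoffs must be strictly increasing, got {tuple(cutoffs)}")
    if isinstance(dist, HbMixture):
        w = np.array([c[0] for c in dist.components])
        m = np.array([c[1] for c in dist.components])
        s = np.array([c[2] for c in dist.components])
        cdf = stats.norm.cdf(np.array([c1, c2, c3])[:, None], loc=m, scale=s)
        bands = np.vstack([1.0 - cdf[2], cdf[2] - cdf[1], cdf[1] - cdf[0], cdf[0]])
        probs = bands @ w
    elif dist.family == "empirical":
        x = np.asarray(dist.sample, dtype=float)
        probs = np.array([
            np.mean(x >= c3),
            np.mean((x >= c2) & (x < c3)),
            np.mean((x >= c1) & (x < c2)),
            np.mean(x < c1),
        ])
        # band frequencies are exact counts/n; do not renormalize
        return AnemiaPrevalence(none=probs[0], mild=probs[1], moderate=probs[2], severe=probs[3])
    else:
        probs = _normal_band_probs(dist.mean, dist.sd, cutoffs)
    probs = np.clip(probs, 0.0, 1.0)
    probs = probs / probs.sum()
    return AnemiaPrevalence(none=probs[0], mild=probs[1], moderate=probs[2], severe=probs[3])


def estimate_decile_means(
    survey: pd.DataFrame,
    hb_column: str = "hb_adjusted_gdl",
    transform: Callable[[float], float] | None = None,
    transform_derivative: Callable[[float], float] | None = None,
) -> pd.DataFrame:
    """Per-decile mean Hb with delta-method standard errors.

    Fits a saturated linear model of Hb on decile indicators (no intercept),
    so each coefficient is the decile mean. Standard errors use the
    heteroskedasticity-robust (HC1) covariance, which for the saturated model
    reduces to per-decile s/sqrt(n); an optional transform g is propagated by
    the delta method, SE(g) = |g'(mean)| * SE (identity by default).

    Returns a frame indexed by decile with columns mean_hb, se, n and a
    boolean ``se_unreliable`` flag for singleton deciles.
    """
    if survey.empty:
        raise ValidationError("survey is empty")
    present = set(survey["decile"].unique())
    missing = sorted(set(range(1, 11)) - present)
    if missing:
        raise ValidationError(f"survey is missing deciles: {missing}")
    dummies = pd.get_dummies(survey["decile"].astype(int), prefix="d", dtype=float)
    fit = sm.OLS(survey[hb_column].astype(float), dummies).fit(cov_type="HC1")
    deciles = sorted(present)
    means = np.array([fit.params[f"d_{d}"] for d in deciles])
    ses = np.array([fit.bse[f"d_{d}"] for d in deciles])
    ns = survey.groupby("decile")[hb_column].size().reindex(deciles).to_numpy()
    if transform is not None:
        if transform_derivative is None:
            raise ValidationError("transform requires transform_derivative for the delta method")
        ses = np.abs([transform_derivative(m) for m in means]) * ses
        means = np.array([transform(m) for m in means])
    out = pd.DataFrame(
        {"mean_hb": means, "se": ses, "n": ns, "se_unreliable": ns <= 1},
        index=pd.Index(deciles, name="decile"),
    )
    out.loc[out["se_unreliable"], "se"] = np.nan
    return out


@dataclass(frozen=True)
class EffectModel:
    """Lagged dose-response of FIC consumption on hemoglobin.

    The Hb gain ramps up with consumption duration and saturates at
    ``max_effect_gdl`` once ``lag_months`` of consumption are reached
    (linear ramp by default; a step alternative for sensitivity use).
    A second daily serving doubles the accumulation rate — the ceiling is
    reached after half the lag — but never raises the ceiling itself beyond
    ``max_effect_gdl * two_serving_cap``.
    """

    max_effect_gdl: float = 0.87
    lag_months: float = 6.0
    ramp: Literal["linear", "step"] = "linear"
    two_serving_cap: float = 1.0

    def __post_init__(self):
        if self.max_effect_gdl < 0:
            raise ValidationError("max_effect_gdl must be >= 0")
        if self.lag_months < 1:
            raise ValidationError("lag_months must be >= 1")
        if not 1.0 <= self.two_serving_cap <= 2.0:
            raise ValidationError("two_serving_cap must lie in [1, 2]")

    def zeroed(self) -> "EffectModel":
        return EffectModel(0.0, self.lag_months, self.ramp, self.two_serving_cap)


def fic_effect(duration_months: float, model: EffectModel | None = None, servings_per_day: float = 1.0) -> float:
    """Hb increase (g/dL) after a given duration of FIC consumption."""
    if duration_months < 0:
        raise ValidationError("duration must be >= 0")
    if servings_per_day <= 0:
        raise ValidationError("servings_per_day must be positive")
    model = model or EffectModel()
    ceiling = model.max_effect_gdl * (model.two_serving_cap if servings_per_day > 1 else 1.0)
    if model.ramp == "step":
        return ceiling if duration_months * servings_per_day >= model.lag_months else 0.0
    frac = min(1.0, duration_months * servings_per_day / model.lag_months)
    return min(ceiling, ceiling * frac)


def counterfactual_distribution(
    dist: HbDistribution,
    profile: ConsumptionProfile,
    model: EffectModel,
    direction: Literal["remove_fic", "add_fic"] = "remove_fic",
) -> HbMixture:
    """Population Hb distribution with the FIC effect removed or added.

    The population is partitioned by consumption duration (the profile's
    duration pmf); each consumer component is shifted by -effect(duration)
    (``remove_fic``) or +effect(duration) (``add_fic``); non-consumers are
    unchanged. The result is the mixture of shifted components.
    """
    if direction not in ("remove_fic", "add_fic"):
        raise ValidationError(f"unknown direction {direction!r}")
    if dist.family != "normal":
        raise ValidationError("counterfactual shifting requires a normal baseline")
    sign = -1.0 if direction == "remove_fic" else 1.0
    comps = []
    for d, p in sorted(profile.duration_pmf.items()):
        if p <= 0:
            continue
        shift = sign * fic_effect(d, model, profile.servings_per_day)
        comps.append((p, dist.mean + shift, dist.sd))
    return HbMixture(components=tuple(comps))
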