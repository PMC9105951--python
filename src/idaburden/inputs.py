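"""Baseline inputs for the burden model.

Three configuration objects feed every downstream stage:

* :class:`PopulationStratum` — one socioeconomic decile of the 2017 Indonesian
  birth cohort (births, mean hemoglobin of 6–23-month-olds, household income
  share).
* :class:`ConsumptionProfile` — fortified-infant-cereal (FIC) consumption:
  the share of children consuming at each month of age (overall and by wealth
  tertile) and the distribution of total consumption duration.
* :class:`ModelParameters` — epidemiological and economic constants (anemia
  cutoffs, iron-deficiency attribution share, disability weights, mortality
  risk, income-loss fraction, wages, growth, discounting, exchange rate).

Configurations are plain text (CSV for the population table, YAML for the
rest) with units spelled out in field names, so a policy analyst can audit
every number that enters the model.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml


class ValidationError(ValueError):
    """An input file or object violates a model contract."""


# Deciles 1-3 are the low-wealth tertile, 4-7 middle, 8-10 high; chosen so the
# tertiles approximate population thirds given the birth counts.
DEFAULT_TERTILE_MAP: dict[int, int] = {
    1: 1, 2: 1, 3: 1, 4: 2, 5: 2, 6: 2, 7: 2, 8: 3, 9: 3, 10: 3,
}

MONTHS = tuple(range(6, 24))  # ages modelled, months
MAX_DURATION = 18  # months of consumption representable in the 6-23 mo window


@dataclass(frozen=True)
class PopulationStratum:
    """One socioeconomic decile of the modelled birth cohort."""

    decile_index: int
    births_thousands: float
    mean_hb_gdl: float
    income_share_pct: float
    hb_sd_gdl: float = 1.4  # only the pooled dispersion is observed
    tertile: int = 0

    def __post_init__(self):
        if not 1 <= self.decile_index <= 10:
            raise ValidationError(f"decile_index {self.decile_index} outside 1-10")
        if self.births_thousands < 0:
            raise ValidationError(f"births_thousands negative in decile {self.decile_index}")
        if not 0 < self.mean_hb_gdl < 25:
            raise ValidationError(f"mean_hb_gdl {self.mean_hb_gdl} implausible in decile {self.decile_index}")
        if self.hb_sd_gdl <= 0:
            raise ValidationError(f"hb_sd_gdl must be positive in decile {self.decile_index}")
        if self.tertile == 0:
            object.__setattr__(self, "tertile", DEFAULT_TERTILE_MAP[self.decile_index])


def validate_strata(strata: Sequence[PopulationStratum]) -> list[PopulationStratum]:
    strata = sorted(strata, key=lambda s: s.decile_index)
    deciles = [s.decile_index for s in strata]
    if deciles != list(range(1, 11)):
        missing = sorted(set(range(1, 11)) - set(deciles))
        raise ValidationError(f"population must contain deciles 1-10 exactly once; missing/duplicated: {missing or deciles}")
    total_share = sum(s.income_share_pct for s in strata)
    if abs(total_share - 100.0) > 0.5:
        raise ValidationError(f"income_share_pct sums to {total_share:.3f}, expected 100 +/- 0.5")
    return list(strata)


def tertile_weights(strata: Sequence[PopulationStratum]) -> np.ndarray:
    """Birth-weighted share of the cohort in each wealth tertile."""
    w = np.zeros(3)
    for s in strata:
        w[s.tertile - 1] += s.births_thousands
    return w / w.sum()


@dataclass
class ConsumptionProfile:
    """FIC consumption by month of age and total duration.

    ``overall_share`` is the authoritative population-level consumption curve;
    ``share_consuming`` carries the per-tertile curves. The two are reconciled
    where the underlying survey roundings allow (see docs/methods.md).
    ``duration_pmf`` is over total months of consumption, 0 meaning never.
    """

    share_consuming: dict[tuple[int, int], float]  # (month, tertile) -> fraction
    duration_pmf: dict[int, float]
    overall_share: dict[int, float] | None = None
    tertile_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    servings_per_day: float = 1.0

    def __post_init__(self):
        for key, v in self.share_consuming.items():
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"share_consuming{key} = {v} outside [0, 1]")
        for d, p in self.duration_pmf.items():
            if p < 0 or d < 0:
                raise ValidationError(f"duration_pmf[{d}] = {p} invalid")
        if abs(sum(self.duration_pmf.values()) - 1.0) > 1e-9:
            raise ValidationError("duration_pmf must sum to 1")
        if self.servings_per_day <= 0:
            raise ValidationError("servings_per_day must be positive")
        if self.overall_share is not None:
            for m, v in self.overall_share.items():
                if not 0.0 <= v <= 1.0:
                    raise ValidationError(f"overall_share[{m}] = {v} outside [0, 1]")

    # -- accessors ---------------------------------------------------------

    @property
    def consumer_fraction(self) -> float:
        """Share of children who ever consume FIC."""
        return 1.0 - self.duration_pmf.get(0, 0.0)

    def share_at(self, month: int, tertile: int | None = None) -> float:
        """Consumption share at a month of age, overall or for one tertile."""
        if tertile is not None:
            return self.share_consuming[(month, tertile)]
        if self.overall_share is not None and month in self.overall_share:
            return self.overall_share[month]
        w = self.tertile_weights
        return sum(self.share_consuming[(month, t)] * w[t - 1] for t in (1, 2, 3))

    def median_duration(self, among_consumers: bool = True) -> float:
        """Median consumption duration (by default among ever-consumers)."""
        items = sorted(self.duration_pmf.items())
        if among_consumers:
            items = [(d, p) for d, p in items if d > 0]
        total = sum(p for _, p in items)
        acc = 0.0
        for d, p in items:
            acc += p
            if acc >= total / 2 - 1e-12:
                return float(d)
        return float(items[-1][0])

    def duration_pmf_consumers(self) -> dict[int, float]:
        """Duration pmf conditional on being a consumer."""
        c = self.consumer_fraction
        if c <= 0:
            return {}
        return {d: p / c for d, p in self.duration_pmf.items() if d > 0}

    def tertile_duration_pmf(self, tertile: int) -> dict[int, float]:
        """Duration pmf for one tertile via the survival-curve construction.

        The share consuming at month ``m`` is read as proportional to
        P(duration >= m - 6), anchored so P(duration >= 1) equals the
        tertile's ever-consumer fraction. The ever-consumer fraction per
        tertile scales the overall 1 - P(0) by the tertile's month-6 share
        relative to the population's.
        """
        peak = max(MONTHS, key=lambda m: self.share_at(m, tertile))
        s_peak = self.share_at(peak, tertile)
        if s_peak <= 0:
            return {0: 1.0}
        ref6 = self.share_at(6)
        c_t = self.consumer_fraction * (self.share_at(6, tertile) / ref6 if ref6 > 0 else 1.0)
        c_t = min(c_t, 1.0)
        surv = {0: 1.0, 1: c_t}
        prev = c_t
        for k in range(2, MAX_DURATION + 1):
            m = 6 + k
            if m <= MONTHS[-1]:
                raw = c_t * min(1.0, self.share_at(m, tertile) / s_peak)
            else:
                # geometric extrapolation of the last observed decay step
                ratio = surv[k - 1] / surv[k - 2] if surv[k - 2] > 0 else 0.0
                raw = surv[k - 1] * ratio
            prev = min(prev, raw)
            surv[k] = prev
        pmf = {0: 1.0 - c_t}
        for k in range(1, MAX_DURATION + 1):
            nxt = surv.get(k + 1, 0.0) if k < MAX_DURATION else 0.0
            pmf[k] = max(surv[k] - nxt, 0.0)
        norm = sum(pmf.values())
        return {d: p / norm for d, p in pmf.items()}


@dataclass
class ModelParameters:
    """Epidemiological and economic constants of the burden model.

    Anemia severity cutoffs follow the WHO convention for 6–59-month-olds
    (severe < 7, moderate < 10, mild < 11 g/dL on altitude-adjusted Hb).
    ``ida_share`` is the fraction of anemia attributed to iron deficiency
    (literature envelope 0.25–0.67 for under-twos). The disability weights,
    mortality risk, cognitive income-loss fraction and wage schedule are
    configurable stand-ins documented in docs/methods.md.
    """

    anemia_cutoffs_gdl: tuple[float, float, float] = (7.0, 10.0, 11.0)
    ida_share: float = 0.46
    dw_mild: float = 0.004
    dw_moderate: float = 0.052
    dw_severe: float = 0.149
    dw_cognitive: float = 0.01
    mortality_risk_severe: float = 0.008
    cognitive_income_loss: float = 0.04
    exposure_years: float = 1.5
    discount_rate: float = 0.03
    income_growth: float = 0.04
    working_ages: tuple[float, float] = (15.0, 65.0)
    life_expectancy_years: float = 71.0
    exchange_rate_idr_per_usd: float = 14582.0
    national_wage_idr_per_year: float = 31_900_000.0
    mean_wage_by_decile_usd: tuple[float, ...] | None = None
    max_effect_gdl: float = 0.87  # ceiling of the FIC hemoglobin response
    effect_lag_months: float = 6.0
    ida_share_override: bool = False

    _FRACTIONS = (
        "ida_share", "dw_mild", "dw_moderate", "dw_severe", "dw_cognitive",
        "mortality_risk_severe", "cognitive_income_loss",
    )

    def __post_init__(self):
        for name in self._FRACTIONS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} = {v} outside [0, 1]")
        if not self.ida_share_override and not 0.25 <= self.ida_share <= 0.67:
            raise ValidationError(
                f"ida_share = {self.ida_share} outside the literature envelope "
                "[0.25, 0.67]; set ida_share_override to use it anyway"
            )
        c1, c2, c3 = self.anemia_cutoffs_gdl
        if not c1 < c2 < c3:
            raise ValidationError(f"anemia cutoffs must be strictly increasing, got {self.anemia_cutoffs_gdl}")
        if self.discount_rate < 0:
            raise ValidationError("discount_rate must be >= 0")
        if self.working_ages[0] >= self.working_ages[1]:
            raise ValidationError("working_ages start must precede end")
        if self.exposure_years < 0 or self.life_expectancy_years <= 0:
            raise ValidationError("exposure_years/life_expectancy out of range")
        if self.max_effect_gdl < 0 or self.effect_lag_months < 1:
            raise ValidationError("max_effect_gdl >= 0 and effect_lag_months >= 1 required")

    @property
    def national_wage_usd(self) -> float:
        return self.national_wage_idr_per_year / self.exchange_rate_idr_per_usd

    def wage_for(self, stratum: PopulationStratum) -> float:
        """Mean annual wage (USD) of a decile.

        Explicit per-decile wages take precedence; otherwise wages scale the
        national mean by the decile's share of household income (a decile at
        exactly 10% of income earns the national mean).
        """
        if self.mean_wage_by_decile_usd is not None:
            return self.mean_wage_by_decile_usd[stratum.decile_index - 1]
        return self.national_wage_usd * stratum.income_share_pct * 10.0 / 100.0

    @property
    def disability_weights(self) -> dict[str, float]:
        return {"mild": self.dw_mild, "moderate": self.dw_moderate, "severe": self.dw_severe}


# ---------------------------------------------------------------------------
# Loaders


def load_population(path: str | Path) -> list[PopulationStratum]:
    """Read the decile population table from CSV and validate it."""
    df = pd.read_csv(path)
    required = {"decile", "births_thousands", "mean_hb_gdl", "income_share_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"population file missing columns: {sorted(missing)}")
    strata = []
    for _, row in df.iterrows():
        for col in required:
            try:
                ok = np.isfinite(float(row[col]))
            except (TypeError, ValueError):
                ok = False
            if not ok:
                raise ValidationError(f"non-numeric value in column {col!r}, decile row {row['decile']!r}")
        kwargs = {}
        if "hb_sd_gdl" in df.columns and np.isfinite(row.get("hb_sd_gdl", np.nan)):
            kwargs["hb_sd_gdl"] = float(row["hb_sd_gdl"])
        if "tertile" in df.columns and np.isfinite(row.get("tertile", np.nan)):
            kwargs["tertile"] = int(row["tertile"])
        strata.append(
            PopulationStratum(
                decile_index=int(row["decile"]),
                births_thousands=float(row["births_thousands"]),
                mean_hb_gdl=float(row["mean_hb_gdl"]),
                income_share_pct=float(row["income_share_pct"]),
                **kwargs,
            )
        )
    return validate_strata(strata)


def write_population(strata: Sequence[PopulationStratum], path: str | Path) -> None:
    pd.DataFrame(
        {
            "decile": [s.decile_index for s in strata],
            "births_thousands": [s.births_thousands for s in strata],
            "mean_hb_gdl": [s.mean_hb_gdl for s in strata],
            "income_share_pct": [s.income_share_pct for s in strata],
            "hb_sd_gdl": [s.hb_sd_gdl for s in strata],
            "tertile": [s.tertile for s in strata],
        }
    ).to_csv(path, index=False)


def load_consumption(path: str | Path) -> ConsumptionProfile:
    """Read a consumption profile from YAML and validate it."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    share = {}
    for key, months in raw["share_consuming_by_tertile"].items():
        t = int(key)
        for m, v in months.items():
            share[(int(m), t)] = float(v)
    pmf = {int(d): float(p) for d, p in raw["duration_pmf"].items()}
    overall = None
    if "overall_share" in raw:
        overall = {int(m): float(v) for m, v in raw["overall_share"].items()}
    tw = tuple(raw.get("tertile_weights", (1 / 3, 1 / 3, 1 / 3)))
    return ConsumptionProfile(
        share_consuming=share,
        duration_pmf=pmf,
        overall_share=overall,
        tertile_weights=tw,
        servings_per_day=float(raw.get("servings_per_day", 1.0)),
    )


def write_consumption(profile: ConsumptionProfile, path: str | Path) -> None:
    by_tertile: dict[int, dict[int, float]] = {1: {}, 2: {}, 3: {}}
    for (m, t), v in sorted(profile.share_consuming.items()):
        by_tertile[t][m] = round(float(v), 6)
    doc = {
        "share_consuming_by_tertile": by_tertile,
        "duration_pmf": {d: float(p) for d, p in sorted(profile.duration_pmf.items())},
        "tertile_weights": [round(float(w), 6) for w in profile.tertile_weights],
        "servings_per_day": profile.servings_per_day,
    }
    if profile.overall_share is not None:
        doc["overall_share"] = {m: round(float(v), 6) for m, v in sorted(profile.overall_share.items())}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


_PARAM_KEYS = {
    "anemia_cutoffs_gdl", "ida_share", "dw_mild", "dw_moderate", "dw_severe",
    "dw_cognitive", "mortality_risk_severe", "cognitive_income_loss",
    "exposure_years", "discount_rate", "income_growth", "working_ages",
    "life_expectancy_years", "exchange_rate_idr_per_usd",
    "national_wage_idr_per_year", "mean_wage_by_decile_usd",
    "max_effect_gdl", "effect_lag_months", "ida_share_override",
}


def load_parameters(path: str | Path) -> ModelParameters:
    """Read model parameters from YAML; unset fields take documented defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _PARAM_KEYS
    if unknown:
        raise ValidationError(f"unknown parameter keys: {sorted(unknown)}")
    for key in ("anemia_cutoffs_gdl", "working_ages", "mean_wage_by_decile_usd"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return ModelParameters(**raw)


def write_parameters(params: ModelParameters, path: str | Path) -> None:
    doc = {
        k: getattr(params, k) for k in sorted(_PARAM_KEYS)
        if getattr(params, k) is not None
    }
    for key in ("anemia_cutoffs_gdl", "working_ages", "mean_wage_by_decile_usd"):
        if key in doc:
            doc[key] = list(doc[key])
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Packaged fixtures


def _data_path(name: str) -> Path:
    return Path(resources.files("idaburden").joinpath("data", name))  # type: ignore[arg-type]


def default_population() -> list[PopulationStratum]:
    """The packaged 2017 Indonesian birth-cohort table by SES decile."""
    return load_population(_data_path("population.csv"))


def default_consumption() -> ConsumptionProfile:
    """The packaged FIC consumption profile (survey anchors, interpolated)."""
    return load_consumption(_data_path("consumption.yaml"))


def default_parameters() -> ModelParameters:
    """The packaged default parameter set (documented stand-ins)."""
    return load_parameters(_data_path("parameters.yaml"))


def build_consumption_profile(
    strata: Sequence[PopulationStratum] | None = None,
    servings_per_day: float = 1.0,
) -> ConsumptionProfile:
    """Construct the default consumption profile from the survey anchors.

    Overall monthly shares interpolate the reported 46/63/25/13/9% at months
    6/7/12/18/23. Tertile curves keep the reported values verbatim at the
    anchor months (6, 12, 23) and at other months follow the interpolated
    tertile pattern rescaled so the births-weighted average reproduces the
    overall curve. The duration distribution places the reported band masses
    (26% never, 17% at 1-2 mo, 21% at 3-5, 25% at 6-11, 11% at 12+) uniformly
    within bands, giving a consumer median of 5 months.
    """
    strata = list(strata) if strata is not None else default_population()
    w = tertile_weights(strata)

    overall_anchors = {6: 0.46, 7: 0.63, 12: 0.25, 18: 0.13, 23: 0.09}
    tert_anchors = {6: (0.39, 0.49, 0.52), 12: (0.18, 0.26, 0.28), 23: (0.06, 0.09, 0.10)}

    months = np.array(MONTHS, dtype=float)
    overall = np.interp(months, sorted(overall_anchors), [overall_anchors[m] for m in sorted(overall_anchors)])
    raw = np.column_stack([
        np.interp(months, sorted(tert_anchors), [tert_anchors[m][t] for m in sorted(tert_anchors)])
        for t in range(3)
    ])  # (18 months, 3 tertiles) interpolated pattern
    weighted = raw @ w
    scaled = raw * (overall / weighted)[:, None]

    share: dict[tuple[int, int], float] = {}
    overall_share: dict[int, float] = {}
    for i, m in enumerate(MONTHS):
        overall_share[m] = float(overall[i])
        vals = tert_anchors.get(m, tuple(scaled[i]))
        for t in (1, 2, 3):
            share[(m, t)] = float(min(1.0, vals[t - 1]))

    bands = {(0, 0): 0.26, (1, 2): 0.17, (3, 5): 0.21, (6, 11): 0.25, (12, MAX_DURATION): 0.11}
    pmf: dict[int, float] = {}
    for (lo, hi), mass in bands.items():
        n = hi - lo + 1
        for d in range(lo, hi + 1):
            pmf[d] = pmf.get(d, 0.0) + mass / n
    total = sum(pmf.values())
    pmf = {d: p / total for d, p in sorted(pmf.items())}

    return ConsumptionProfile(
        share_consuming=share,
        duration_pmf=pmf,
        overall_share=overall_share,
        tertile_weights=tuple(float(x) for x in w),
        servings_per_day=servings_per_day,
    )
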