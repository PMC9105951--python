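"""Lifetime burden accounting: production losses and DALYs.

Converts iron-deficiency-anemia (IDA) prevalence per socioeconomic stratum
into the three reported channels:

* impaired physical activity — YLD during the exposure window, weighted by
  severity-specific disability weights;
* cognitive impairment — lifelong YLD with a cognitive-sequel weight, plus
  production losses as a fraction of discounted lifetime earnings;
* mortality — deaths among severe cases, valued as discounted years of life
  lost and as fully lost lifetime earnings.

Money is reported in millions of USD, DALYs in thousands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .hemoglobin import AnemiaPrevalence
from .inputs import ModelParameters, PopulationStratum, ValidationError

CHANNELS = (
    "losses_cognitive", "losses_mortality", "losses_total",
    "dalys_physical", "dalys_cognitive", "dalys_mortality", "dalys_total",
)


@dataclass(frozen=True)
class IncomeStream:
    """An annual wage stream over working ages, discounted to a valuation age."""

    start_age: float
    end_age: float
    annual_wage_usd: float
    growth: float
    discount: float
    valuation_age: float = 1.0

    def __post_init__(self):
        if self.start_age >= self.end_age:
            raise ValidationError("start_age must precede end_age")
        if self.discount <= -1.0:
            raise ValidationError("discount must exceed -1")


def present_value(stream: IncomeStream) -> float:
    """Present value (USD) of the income stream at the valuation age.

    Sums wage * (1+growth)^(a - v) / (1+discount)^(a - v) over integer ages
    a in [start_age, end_age).
    """
    ages = np.arange(math.ceil(stream.start_age), math.ceil(stream.end_age))
    t = ages - stream.valuation_age
    ratio = (1.0 + stream.growth) / (1.0 + stream.discount)
    return float(stream.annual_wage_usd * np.sum(ratio ** t))


def discounted_life_years(years: float, discount: float) -> float:
    """Discounted person-years over a horizon, last partial year prorated."""
    if years < 0:
        raise ValidationError("years must be >= 0")
    if years == 0:
        return 0.0
    full = int(math.floor(years))
    t = np.arange(full + 1, dtype=float)
    weights = np.ones(full + 1)
    weights[-1] = years - full
    if weights[-1] == 0:
        t, weights = t[:-1], weights[:-1]
    return float(np.sum(weights / (1.0 + discount) ** t))


def ida_prevalence(anemia: AnemiaPrevalence, ida_share: float) -> AnemiaPrevalence:
    """Restrict anemia prevalence to the iron-deficiency-attributable part.

    Each severity fraction is multiplied by the attribution share; the
    'none' category absorbs the remainder so the fractions still sum to 1.
    """
    if not 0.0 <= ida_share <= 1.0:
        raise ValidationError(f"ida_share {ida_share} outside [0, 1]")
    mild = anemia.mild * ida_share
    moderate = anemia.moderate * ida_share
    severe = anemia.severe * ida_share
    return AnemiaPrevalence(none=1.0 - mild - moderate - severe, mild=mild, moderate=moderate, severe=severe)


@dataclass(frozen=True)
class BurdenResult:
    """Burden of IDA: production losses (millions USD) and DALYs (thousands)."""

    losses_cognitive: float
    losses_mortality: float
    dalys_physical: float
    dalys_cognitive: float
    dalys_mortality: float
    per_stratum: pd.DataFrame | None = field(default=None, compare=False)

    def __post_init__(self):
        for name in ("losses_cognitive", "losses_mortality", "dalys_physical",
                     "dalys_cognitive", "dalys_mortality"):
            if getattr(self, name) < -1e-9:
                raise ValidationError(f"{name} is negative")

    @property
    def losses_total(self) -> float:
        return self.losses_cognitive + self.losses_mortality

    @property
    def dalys_total(self) -> float:
        return self.dalys_physical + self.dalys_cognitive + self.dalys_mortality

    def component(self, name: str) -> float:
        if name == "losses_total":
            return self.losses_total
        if name == "dalys_total":
            return self.dalys_total
        return getattr(self, name)

    def as_dict(self) -> dict[str, float]:
        return {name: self.component(name) for name in CHANNELS}

    def __add__(self, other: "BurdenResult") -> "BurdenResult":
        return BurdenResult(
            losses_cognitive=self.losses_cognitive + other.losses_cognitive,
            losses_mortality=self.losses_mortality + other.losses_mortality,
            dalys_physical=self.dalys_physical + other.dalys_physical,
            dalys_cognitive=self.dalys_cognitive + other.dalys_cognitive,
            dalys_mortality=self.dalys_mortality + other.dalys_mortality,
        )


def compute_burden(
    strata: Sequence[PopulationStratum],
    prevalence_by_stratum: Sequence[AnemiaPrevalence],
    params: ModelParameters,
) -> BurdenResult:
    """Burden of IDA given IDA-restricted prevalence per stratum.

    Affected counts are births x prevalence per severity. Physical-activity
    DALYs accrue over the exposure window with severity-specific disability
    weights; cognitive YLD and income losses apply to all IDA-positive
    children over (discounted) remaining life; mortality applies the severe
    case-fatality risk, valued as discounted life-years lost and as the full
    discounted income stream.
    """
    if len(strata) != len(prevalence_by_stratum):
        raise ValidationError(
            f"{len(strata)} strata but {len(prevalence_by_stratum)} prevalence entries"
        )
    dly_life = discounted_life_years(params.life_expectancy_years, params.discount_rate)
    rows = []
    for stratum, prev in zip(strata, prevalence_by_stratum):
        n_mild = stratum.births_thousands * prev.mild
        n_moderate = stratum.births_thousands * prev.moderate
        n_severe = stratum.births_thousands * prev.severe
        n_ida = n_mild + n_moderate + n_severe

        pv = present_value(IncomeStream(
            start_age=params.working_ages[0],
            end_age=params.working_ages[1],
            annual_wage_usd=params.wage_for(stratum),
            growth=params.income_growth,
            discount=params.discount_rate,
        ))

        dalys_physical = (
            n_mild * params.dw_mild + n_moderate * params.dw_moderate + n_severe * params.dw_severe
        ) * params.exposure_years
        dalys_cognitive = n_ida * params.dw_cognitive * dly_life
        deaths = n_severe * params.mortality_risk_severe
        dalys_mortality = deaths * dly_life

        losses_cognitive = n_ida * params.cognitive_income_loss * pv / 1000.0  # kUSD -> MUSD
        losses_mortality = deaths * pv / 1000.0

        rows.append({
            "decile": stratum.decile_index,
            "tertile": stratum.tertile,
            "n_ida_thousands": n_ida,
            "deaths_thousands": deaths,
            "losses_cognitive": losses_cognitive,
            "losses_mortality": losses_mortality,
            "dalys_physical": dalys_physical,
            "dalys_cognitive": dalys_cognitive,
            "dalys_mortality": dalys_mortality,
        })
    per_stratum = pd.DataFrame(rows).set_index("decile")
    totals = per_stratum[["losses_cognitive", "losses_mortality", "dalys_physical",
                          "dalys_cognitive", "dalys_mortality"]].sum()
    return BurdenResult(per_stratum=per_stratum, **totals.to_dict())
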