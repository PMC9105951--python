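"""Policy scenarios and paired burden comparisons.

Each scenario is a transformation of the consumption profile and/or the
dose-response model:

* ``NO_FORTIFICATION`` — cereals stay on the menu but carry no iron effect
  (the counterfactual that defines the current benefit of fortification);
* ``CURRENT`` — observed consumption, one serving per day (identity);
* ``EXTEND_SHORT_PLUS2`` — short consumers (duration below a threshold,
  default 3 months) consume 2 months longer;
* ``LIFT_LOWEST_TO_MIDDLE`` — the lowest wealth tertile adopts the middle
  tertile's consumption curve (evaluated on the lowest-tertile
  subpopulation);
* ``LIFT_AND_EXTEND`` — the lift plus a 2-month extension for durations
  under 5 months;
* ``TWO_SERVINGS_ALL_PLUS2`` — every consumer takes two servings per day and
  short consumers get the 2-month extension.

Scenario evaluation shifts each duration component of the population Hb
mixture by the change in the dose-response effect, recomputes anemia and IDA
prevalence per stratum, and re-runs the burden engine. Comparisons report
absolute differences and percentages relative to the current-consumption
scenario, as in the published difference rows.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Sequence

from .burden import CHANNELS, BurdenResult, compute_burden, ida_prevalence
from .hemoglobin import (
    EffectModel,
    HbMixture,
    fic_effect,
    prevalence_from_distribution,
)
from .inputs import ConsumptionProfile, ModelParameters, PopulationStratum, ValidationError


class ScenarioKind(Enum):
    NO_FORTIFICATION = "no_fortification"
    CURRENT = "current"
    EXTEND_SHORT_PLUS2 = "extend_short_plus2"
    LIFT_LOWEST_TO_MIDDLE = "lift_lowest_to_middle"
    LIFT_AND_EXTEND = "lift_and_extend"
    TWO_SERVINGS_ALL_PLUS2 = "two_servings_all_plus2"


LIFT_KINDS = (ScenarioKind.LIFT_LOWEST_TO_MIDDLE, ScenarioKind.LIFT_AND_EXTEND)


@dataclass(frozen=True)
class Scenario:
    """A policy scenario with its duration threshold and extension length."""

    kind: ScenarioKind
    short_duration_threshold: float | None = None
    extension_months: float = 2.0

    def __post_init__(self):
        if self.extension_months < 0:
            raise ValidationError("extension_months must be >= 0")
        if self.short_duration_threshold is None:
            default = 5.0 if self.kind == ScenarioKind.LIFT_AND_EXTEND else 3.0
            object.__setattr__(self, "short_duration_threshold", default)
        if self.short_duration_threshold < 0:
            raise ValidationError("short_duration_threshold must be >= 0")


# A duration map couples each slice of the population (weight) to its
# consumption duration and servings before and after the scenario.
DurationMap = list[tuple[float, float, float, float, float]]  # (w, d_old, s_old, d_new, s_new)


def _comonotone_coupling(pmf_old: dict[int, float], pmf_new: dict[int, float]) -> list[tuple[float, float, float]]:
    """Quantile (comonotone) coupling of two duration pmfs: (weight, old, new)."""
    old = sorted((d, p) for d, p in pmf_old.items() if p > 0)
    new = sorted((d, p) for d, p in pmf_new.items() if p > 0)
    out = []
    i = j = 0
    ro, rn = old[0][1], new[0][1]
    while i < len(old) and j < len(new):
        w = min(ro, rn)
        if w > 1e-15:
            out.append((w, float(old[i][0]), float(new[j][0])))
        ro -= w
        rn -= w
        if ro <= 1e-15:
            i += 1
            ro = old[i][1] if i < len(old) else 0.0
        if rn <= 1e-15:
            j += 1
            rn = new[j][1] if j < len(new) else 0.0
    return out


def _extend(d: float, threshold: float, extension: float) -> float:
    return d + extension if 0 < d < threshold else d


def duration_map(profile: ConsumptionProfile, scenario: Scenario) -> DurationMap:
    """The population's (old duration, new duration, servings) coupling."""
    kind = scenario.kind
    s0 = profile.servings_per_day
    thr = scenario.short_duration_threshold
    ext = scenario.extension_months
    if kind in (ScenarioKind.CURRENT, ScenarioKind.NO_FORTIFICATION):
        return [(p, float(d), s0, float(d), s0) for d, p in sorted(profile.duration_pmf.items()) if p > 0]
    if kind == ScenarioKind.EXTEND_SHORT_PLUS2:
        return [(p, float(d), s0, _extend(d, thr, ext), s0)
                for d, p in sorted(profile.duration_pmf.items()) if p > 0]
    if kind == ScenarioKind.TWO_SERVINGS_ALL_PLUS2:
        return [(p, float(d), s0, _extend(d, thr, ext), 2.0 if d > 0 else s0)
                for d, p in sorted(profile.duration_pmf.items()) if p > 0]
    if kind in LIFT_KINDS:
        pmf1 = profile.tertile_duration_pmf(1)
        pmf2 = profile.tertile_duration_pmf(2)
        coupled = _comonotone_coupling(pmf1, pmf2)
        out: DurationMap = []
        for w, d_old, d_new in coupled:
            if kind == ScenarioKind.LIFT_AND_EXTEND:
                d_new = _extend(d_new, thr, ext)
            out.append((w, d_old, s0, d_new, s0))
        return out
    raise ValidationError(f"unknown scenario kind {kind!r}")


def apply_scenario(
    profile: ConsumptionProfile, model: EffectModel, scenario: Scenario
) -> tuple[ConsumptionProfile, EffectModel]:
    """Transformed (consumption profile, effect model) under a scenario."""
    kind = scenario.kind
    if kind == ScenarioKind.CURRENT:
        return profile, model
    if kind == ScenarioKind.NO_FORTIFICATION:
        return profile, model.zeroed()
    dmap = duration_map(profile, scenario)
    new_pmf: dict[int, float] = {}
    for w, _, _, d_new, _ in dmap:
        key = int(round(d_new))
        new_pmf[key] = new_pmf.get(key, 0.0) + w
    share = dict(profile.share_consuming)
    if kind in LIFT_KINDS:
        for (m, t), v in profile.share_consuming.items():
            if t == 2:
                share[(m, 1)] = v
    servings = 2.0 if kind == ScenarioKind.TWO_SERVINGS_ALL_PLUS2 else profile.servings_per_day
    new_profile = replace(
        profile,
        share_consuming=share,
        duration_pmf={d: p for d, p in sorted(new_pmf.items())},
        servings_per_day=servings,
    )
    return new_profile, model


def scenario_mixture(
    stratum: PopulationStratum,
    dmap: DurationMap,
    model_old: EffectModel,
    model_new: EffectModel,
) -> HbMixture:
    """Stratum Hb mixture after re-assigning durations/servings per the map.

    The observed stratum distribution is treated as the current-consumption
    baseline; each population slice is shifted by the change in the
    dose-response effect between its old and new exposure.
    """
    comps = []
    for w, d_old, s_old, d_new, s_new in dmap:
        shift = fic_effect(d_new, model_new, s_new) - fic_effect(d_old, model_old, s_old)
        comps.append((w, stratum.mean_hb_gdl + shift, stratum.hb_sd_gdl))
    return HbMixture(components=tuple(comps))


def evaluate_scenario(
    strata: Sequence[PopulationStratum],
    profile: ConsumptionProfile,
    model: EffectModel,
    params: ModelParameters,
    scenario: Scenario,
    restrict_tertile: int | None = None,
    dmap: DurationMap | None = None,
) -> BurdenResult:
    """Burden of IDA under one scenario.

    The lift scenarios are evaluated on the lowest-tertile subpopulation with
    tertile-specific duration distributions; other scenarios use the whole
    population and the overall duration distribution.
    """
    if scenario.kind in LIFT_KINDS and restrict_tertile is None:
        restrict_tertile = 1
    if restrict_tertile is not None:
        strata = [s for s in strata if s.tertile == restrict_tertile]
        if not strata:
            raise ValidationError(f"no strata in tertile {restrict_tertile}")
    if dmap is None:
        dmap = duration_map(profile, scenario)
    model_new = model.zeroed() if scenario.kind == ScenarioKind.NO_FORTIFICATION else model
    prevalences = []
    for stratum in strata:
        mix = scenario_mixture(stratum, dmap, model, model_new)
        anemia = prevalence_from_distribution(mix, params.anemia_cutoffs_gdl)
        prevalences.append(ida_prevalence(anemia, params.ida_share))
    return compute_burden(strata, prevalences, params)


@dataclass(frozen=True)
class ComparisonTable:
    """A paired scenario comparison in the shape of the published tables.

    ``current`` is the current-consumption run (the percentage denominator);
    ``other`` is the counterfactual or policy scenario. Differences are
    absolute values; percentages are relative to ``current``.
    """

    current: BurdenResult
    other: BurdenResult
    label: str = ""

    def abs_diff(self, channel: str) -> float:
        return abs(self.other.component(channel) - self.current.component(channel))

    def pct_diff(self, channel: str) -> float:
        base = self.current.component(channel)
        return 100.0 * self.abs_diff(channel) / base if base != 0 else 0.0

    def as_dict(self) -> dict[str, dict[str, float]]:
        return {
            channel: {
                "current": self.current.component(channel),
                "other": self.other.component(channel),
                "abs_diff": self.abs_diff(channel),
                "pct_diff": self.pct_diff(channel),
            }
            for channel in CHANNELS
        }


def compare_burden(current: BurdenResult, other: BurdenResult, label: str = "") -> ComparisonTable:
    """Pair two burden results into a difference table."""
    return ComparisonTable(current=current, other=other, label=label)


def run_full_analysis(
    strata: Sequence[PopulationStratum],
    profile: ConsumptionProfile,
    model: EffectModel,
    params: ModelParameters,
    scenarios: Sequence[Scenario],
) -> dict[ScenarioKind, ComparisonTable]:
    """Evaluate the current scenario and each policy scenario, paired.

    Whole-population scenarios are compared against the whole-population
    current run; lift scenarios against the lowest-tertile current run
    (evaluated with the lowest tertile's own duration distribution).
    Deterministic given its inputs.
    """
    current_scenario = Scenario(ScenarioKind.CURRENT)
    current_all = evaluate_scenario(strata, profile, model, params, current_scenario)
    current_t1: BurdenResult | None = None
    out: dict[ScenarioKind, ComparisonTable] = {}
    for scenario in scenarios:
        if scenario.kind in LIFT_KINDS:
            if current_t1 is None:
                pmf1 = profile.tertile_duration_pmf(1)
                dmap1 = [(p, float(d), profile.servings_per_day, float(d), profile.servings_per_day)
                         for d, p in sorted(pmf1.items()) if p > 0]
                current_t1 = evaluate_scenario(
                    strata, profile, model, params, current_scenario,
                    restrict_tertile=1, dmap=dmap1,
                )
            other = evaluate_scenario(strata, profile, model, params, scenario)
            out[scenario.kind] = compare_burden(current_t1, other, scenario.kind.value)
        elif scenario.kind == ScenarioKind.CURRENT:
            out[scenario.kind] = compare_burden(current_all, current_all, scenario.kind.value)
        else:
            other = evaluate_scenario(strata, profile, model, params, scenario)
            out[scenario.kind] = compare_burden(current_all, other, scenario.kind.value)
    return out
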