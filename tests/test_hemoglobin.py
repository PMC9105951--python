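"""Hemoglobin machinery: altitude adjustment, classification, prevalence,
decile-mean estimation, the dose-response, and counterfactual shifting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from idaburden import (
    AltitudeTable,
    EffectModel,
    HbDistribution,
    ValidationError,
    adjust_for_altitude,
    classify_anemia,
    counterfactual_distribution,
    estimate_decile_means,
    fic_effect,
    prevalence_from_distribution,
)
from idaburden.inputs import ConsumptionProfile

CUTOFFS = (7.0, 10.0, 11.0)


class TestAltitude:
    @pytest.mark.parametrize("hb,alt,expected", [
        (11.0, 500, 11.0),     # below first breakpoint: no adjustment
        (10.0, 0, 10.0),       # sea level
        (11.0, 1500, 10.5),
        (11.0, 999, 11.0),
        (11.0, 4500, 6.5),
    ])
    def test_band_lookup(self, hb, alt, expected):
        assert adjust_for_altitude(hb, alt) == pytest.approx(expected)

    def test_negative_altitude_rejected(self):
        with pytest.raises(ValidationError):
            adjust_for_altitude(11.0, -10)

    def test_decrements_must_be_monotone(self):
        with pytest.raises(ValidationError):
            AltitudeTable(breakpoints=((1000.0, 0.5), (2000.0, 0.2)))


class TestClassification:
    @pytest.mark.parametrize("hb,severity", [
        (6.9, "severe"),
        (7.0, "moderate"),
        (9.99, "moderate"),
        (10.0, "mild"),
        (10.5, "mild"),
        (11.0, "none"),   # boundary inclusive on the healthy side
        (13.0, "none"),
    ])
    def test_severity_bands(self, hb, severity):
        assert classify_anemia(hb, CUTOFFS) == severity

    def test_non_increasing_cutoffs_rejected(self):
        with pytest.raises(ValidationError):
            classify_anemia(10.0, (10.0, 7.0, 11.0))


class TestPrevalence:
    def test_normal_severe_fraction_matches_monte_carlo(self):
        """Band probabilities from the normal CDF agree with a 10^7-draw
        Monte Carlo oracle to 3 significant figures."""
        prev = prevalence_from_distribution(HbDistribution(10.5, 1.4), CUTOFFS)
        rng = np.random.default_rng(2024)
        draws = rng.normal(10.5, 1.4, size=10_000_000)
        mc_severe = np.mean(draws < 7.0)
        assert prev.severe == pytest.approx(0.00621, abs=2e-4)
        assert prev.severe == pytest.approx(mc_severe, rel=5e-2, abs=1e-4)
        mc_mild = np.mean((draws >= 10.0) & (draws < 11.0))
        assert prev.mild == pytest.approx(mc_mild, abs=5e-4)

    def test_degenerate_mass_above_cutoffs(self):
        prev = prevalence_from_distribution(HbDistribution(12.0, 1e-4), CUTOFFS)
        assert prev.none == pytest.approx(1.0, abs=1e-12)
        assert prev.severe == pytest.approx(0.0, abs=1e-12)

    def test_empirical_one_value_per_band(self):
        dist = HbDistribution(0, 0, family="empirical", sample=(6.0, 8.0, 10.5, 12.0))
        prev = prevalence_from_distribution(dist, CUTOFFS)
        assert prev.as_array() == pytest.approx([0.25, 0.25, 0.25, 0.25])

    def test_empirical_equals_classify_and_count_exactly(self):
        rng = np.random.default_rng(7)
        sample = tuple(rng.normal(10.5, 1.4, size=503))
        prev = prevalence_from_distribution(
            HbDistribution(0, 0, family="empirical", sample=sample), CUTOFFS
        )
        counts = {"none": 0, "mild": 0, "moderate": 0, "severe": 0}
        for hb in sample:
            counts[classify_anemia(hb, CUTOFFS)] += 1
        for sev, count in counts.items():
            assert getattr(prev, sev) == count / len(sample)

    def test_empirical_requires_sample(self):
        with pytest.raises(ValidationError):
            HbDistribution(10.5, 1.4, family="empirical", sample=())

    @given(mean=st.floats(8.0, 14.0), bump=st.floats(0.01, 2.0), sd=st.floats(0.5, 3.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_raising_the_mean_weakly_lowers_anemia(self, mean, bump, sd):
        lo = prevalence_from_distribution(HbDistribution(mean, sd), CUTOFFS)
        hi = prevalence_from_distribution(HbDistribution(mean + bump, sd), CUTOFFS)
        assert hi.any_anemia <= lo.any_anemia + 1e-12

    @given(mean=st.floats(6.0, 16.0), sd=st.floats(0.2, 4.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_fractions_conserve_mass(self, mean, sd):
        prev = prevalence_from_distribution(HbDistribution(mean, sd), CUTOFFS)
        assert prev.as_array().sum() == pytest.approx(1.0, abs=1e-9)


class TestDecileMeans:
    @staticmethod
    def _survey(rng, n=2000):
        deciles = rng.integers(1, 11, size=n)
        hb = rng.normal(10.5, 1.4, size=n)
        return pd.DataFrame({"decile": deciles, "hb_adjusted_gdl": hb})

    def test_constant_decile_has_exact_mean_and_zero_se(self):
        rng = np.random.default_rng(0)
        survey = self._survey(rng)
        survey.loc[survey["decile"] == 3, "hb_adjusted_gdl"] = 10.5
        out = estimate_decile_means(survey)
        assert out.loc[3, "mean_hb"] == pytest.approx(10.5, abs=1e-10)
        assert out.loc[3, "se"] == pytest.approx(0.0, abs=1e-10)

    def test_estimates_are_group_means(self):
        rng = np.random.default_rng(1)
        survey = self._survey(rng)
        out = estimate_decile_means(survey)
        direct = survey.groupby("decile")["hb_adjusted_gdl"].mean()
        assert out["mean_hb"].to_numpy() == pytest.approx(direct.to_numpy(), abs=1e-9)

    def test_singleton_decile_flagged_unreliable(self):
        rng = np.random.default_rng(2)
        survey = self._survey(rng)
        survey = survey[survey["decile"] != 5]
        single = pd.DataFrame({"decile": [5], "hb_adjusted_gdl": [9.87]})
        out = estimate_decile_means(pd.concat([survey, single], ignore_index=True))
        assert out.loc[5, "mean_hb"] == pytest.approx(9.87)
        assert out.loc[5, "se_unreliable"]
        assert np.isnan(out.loc[5, "se"])

    def test_missing_decile_listed(self):
        rng = np.random.default_rng(3)
        survey = self._survey(rng)
        with pytest.raises(ValidationError, match=r"\[7\]"):
            estimate_decile_means(survey[survey["decile"] != 7])

    def test_delta_method_transform(self):
        rng = np.random.default_rng(4)
        survey = self._survey(rng)
        base = estimate_decile_means(survey)
        logged = estimate_decile_means(survey, transform=np.log,
                                       transform_derivative=lambda m: 1.0 / m)
        assert logged["mean_hb"].to_numpy() == pytest.approx(np.log(base["mean_hb"].to_numpy()))
        assert logged["se"].to_numpy() == pytest.approx(
            base["se"].to_numpy() / base["mean_hb"].to_numpy())


class TestEffect:
    @pytest.mark.parametrize("duration,expected", [
        (0.0, 0.0),
        (3.0, 0.435),   # linear ramp: half the lag, half the ceiling
        (6.0, 0.87),
        (12.0, 0.87),
    ])
    def test_linear_ramp(self, duration, expected, effect_model):
        assert fic_effect(duration, effect_model) == pytest.approx(expected)

    def test_negative_duration_rejected(self, effect_model):
        with pytest.raises(ValidationError):
            fic_effect(-1.0, effect_model)

    def test_two_servings_halve_the_lag_but_not_the_ceiling(self, effect_model):
        assert fic_effect(3.0, effect_model, servings_per_day=2) == pytest.approx(0.87)
        assert fic_effect(1.5, effect_model, servings_per_day=2) == pytest.approx(0.435)
        assert fic_effect(12.0, effect_model, servings_per_day=2) == pytest.approx(0.87)

    def test_step_ramp(self):
        model = EffectModel(ramp="step")
        assert fic_effect(5.9, model) == 0.0
        assert fic_effect(6.0, model) == pytest.approx(0.87)

    @given(d1=st.floats(0, 20), d2=st.floats(0, 20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_effect_is_monotone_and_capped(self, d1, d2, effect_model):
        lo, hi = sorted([d1, d2])
        assert fic_effect(lo, effect_model) <= fic_effect(hi, effect_model) + 1e-12
        assert 0.0 <= fic_effect(hi, effect_model) <= 0.87 + 1e-12


class TestCounterfactual:
    def test_null_exposure_is_identity(self, effect_model):
        profile = ConsumptionProfile(share_consuming={}, duration_pmf={0: 1.0})
        dist = HbDistribution(10.5, 1.4)
        mix = counterfactual_distribution(dist, profile, effect_model)
        assert mix.mean == pytest.approx(10.5, abs=1e-12)
        assert mix.sd == pytest.approx(1.4, abs=1e-12)

    def test_saturated_consumers_shift_by_ceiling_times_share(self, effect_model):
        profile = ConsumptionProfile(share_consuming={}, duration_pmf={0: 0.3, 6: 0.3, 9: 0.4})
        dist = HbDistribution(10.5, 1.4)
        mix = counterfactual_distribution(dist, profile, effect_model, "remove_fic")
        assert mix.mean == pytest.approx(10.5 - 0.87 * 0.7, abs=1e-12)

    def test_remove_then_add_recovers_the_mean(self, profile, effect_model):
        dist = HbDistribution(10.5, 1.4)
        removed = counterfactual_distribution(dist, profile, effect_model, "remove_fic")
        added = counterfactual_distribution(dist, profile, effect_model, "add_fic")
        assert (removed.mean + added.mean) / 2 == pytest.approx(dist.mean, abs=1e-9)
        mean_effect = dist.mean - removed.mean
        assert added.mean - dist.mean == pytest.approx(mean_effect, abs=1e-9)

    def test_removal_raises_anemia(self, profile, effect_model, params):
        dist = HbDistribution(10.5, 1.4)
        base = prevalence_from_distribution(dist, params.anemia_cutoffs_gdl)
        removed = prevalence_from_distribution(
            counterfactual_distribution(dist, profile, effect_model),
            params.anemia_cutoffs_gdl,
        )
        assert removed.any_anemia > base.any_anemia
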