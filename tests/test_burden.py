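"""Burden engine: discounting oracles, IDA attribution, channel accounting."""

import dataclasses

import numpy as np
import pytest

from idaburden import (
    AnemiaPrevalence,
    IncomeStream,
    ModelParameters,
    PopulationStratum,
    ValidationError,
    compute_burden,
    discounted_life_years,
    ida_prevalence,
    present_value,
)


def pv_loop_oracle(stream: IncomeStream) -> float:
    """Brute-force year-by-year summation."""
    total = 0.0
    age = int(np.ceil(stream.start_age))
    while age < stream.end_age:
        t = age - stream.valuation_age
        total += stream.annual_wage_usd * (1 + stream.growth) ** t / (1 + stream.discount) ** t
        age += 1
    return total


class TestPresentValue:
    def test_growth_equal_discount_cancels(self):
        stream = IncomeStream(15, 65, 1234.5, growth=0.03, discount=0.03)
        assert present_value(stream) == pytest.approx(50 * 1234.5, rel=1e-12)

    def test_zero_wage(self):
        assert present_value(IncomeStream(15, 65, 0.0, 0.04, 0.03)) == 0.0

    def test_matches_loop_oracle(self):
        stream = IncomeStream(15, 65, 1000.0, growth=0.0, discount=0.03, valuation_age=1)
        assert present_value(stream) == pytest.approx(pv_loop_oracle(stream), rel=1e-6)

    def test_matches_loop_oracle_over_random_parameterizations(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            stream = IncomeStream(
                start_age=float(rng.integers(10, 30)),
                end_age=float(rng.integers(40, 90)),
                annual_wage_usd=float(rng.uniform(100, 20000)),
                growth=float(rng.uniform(-0.02, 0.08)),
                discount=float(rng.uniform(0.0, 0.1)),
                valuation_age=float(rng.uniform(0, 5)),
            )
            assert present_value(stream) == pytest.approx(pv_loop_oracle(stream), rel=1e-6)

    def test_strictly_decreasing_in_discount(self):
        pvs = [present_value(IncomeStream(15, 65, 1000.0, 0.02, r)) for r in (0.03, 0.05, 0.08)]
        assert pvs[0] > pvs[1] > pvs[2]

    def test_extreme_discount_rejected(self):
        with pytest.raises(ValidationError):
            IncomeStream(15, 65, 1000.0, 0.0, -1.5)


class TestDiscountedLifeYears:
    def test_undiscounted(self):
        assert discounted_life_years(10, 0.0) == pytest.approx(10.0)

    def test_empty_horizon(self):
        assert discounted_life_years(0, 0.03) == 0.0

    def test_matches_geometric_closed_form(self):
        v = 1.03
        expected = (1 - v ** -70) / (1 - 1 / v)
        assert discounted_life_years(70, 0.03) == pytest.approx(expected, rel=1e-9)

    def test_partial_last_year_prorated(self):
        full = discounted_life_years(10, 0.05)
        half = discounted_life_years(10.5, 0.05)
        assert half == pytest.approx(full + 0.5 * 1.05 ** -10, rel=1e-12)


class TestIdaAttribution:
    ANEMIA = AnemiaPrevalence(none=0.369, mild=0.304, moderate=0.314, severe=0.013)

    def test_null_attribution(self):
        out = ida_prevalence(self.ANEMIA, 0.0)
        assert out.as_array()[1:] == pytest.approx([0, 0, 0])
        assert out.none == 1.0

    def test_full_attribution_is_identity(self):
        out = ida_prevalence(self.ANEMIA, 1.0)
        assert out.as_array() == pytest.approx(self.ANEMIA.as_array())

    def test_elementwise_product(self):
        out = ida_prevalence(self.ANEMIA, 0.46)
        assert (out.mild, out.moderate, out.severe) == pytest.approx(
            (0.13984, 0.14444, 0.00598))
        assert out.as_array().sum() == pytest.approx(1.0, abs=1e-12)


def _stratum(births=100.0, decile=1, income=10.0):
    return PopulationStratum(decile_index=decile, births_thousands=births,
                             mean_hb_gdl=10.5, income_share_pct=income)


class TestComputeBurden:
    IDA = AnemiaPrevalence(none=0.8, mild=0.1, moderate=0.08, severe=0.02)

    def test_null_epidemic_is_all_zeros(self, params):
        zero = AnemiaPrevalence(1.0, 0.0, 0.0, 0.0)
        result = compute_burden([_stratum()], [zero], params)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in result.as_dict().values())

    def test_linearity_in_cognitive_income_loss(self, params):
        base = compute_burden([_stratum()], [self.IDA], params)
        doubled_params = dataclasses.replace(params, cognitive_income_loss=2 * params.cognitive_income_loss)
        doubled = compute_burden([_stratum()], [self.IDA], doubled_params)
        assert doubled.losses_cognitive == pytest.approx(2 * base.losses_cognitive, rel=1e-12)
        assert doubled.losses_mortality == pytest.approx(base.losses_mortality, rel=1e-12)
        assert doubled.dalys_total == pytest.approx(base.dalys_total, rel=1e-12)

    def test_single_stratum_hand_oracle(self):
        """One stratum with hand-set parameters equals a spreadsheet-style
        closed-form computation."""
        params = ModelParameters(
            ida_share=0.5, dw_mild=0.004, dw_moderate=0.05, dw_severe=0.149,
            dw_cognitive=0.01, mortality_risk_severe=0.01,
            cognitive_income_loss=0.05, exposure_years=1.5,
            discount_rate=0.03, income_growth=0.03, working_ages=(15.0, 65.0),
            life_expectancy_years=10.0, mean_wage_by_decile_usd=(200.0,) * 10,
        )
        stratum = _stratum(births=100.0)
        prev = AnemiaPrevalence(none=0.9, mild=0.05, moderate=0.04, severe=0.01)
        result = compute_burden([stratum], [prev], params)
        pv = 200.0 * 50  # growth == discount
        dly = sum(1.03 ** -t for t in range(10))
        n_mild, n_mod, n_sev = 5.0, 4.0, 1.0
        n_ida = 10.0
        deaths = n_sev * 0.01
        assert result.dalys_physical == pytest.approx(
            (n_mild * 0.004 + n_mod * 0.05 + n_sev * 0.149) * 1.5, rel=1e-9)
        assert result.dalys_cognitive == pytest.approx(n_ida * 0.01 * dly, rel=1e-9)
        assert result.dalys_mortality == pytest.approx(deaths * dly, rel=1e-9)
        assert result.losses_cognitive == pytest.approx(n_ida * 0.05 * pv / 1000, rel=1e-9)
        assert result.losses_mortality == pytest.approx(deaths * pv / 1000, rel=1e-9)

    def test_additive_over_strata(self, params):
        s1, s2 = _stratum(decile=1, income=5.0), _stratum(births=50.0, decile=2, income=15.0)
        p1 = self.IDA
        p2 = AnemiaPrevalence(none=0.9, mild=0.05, moderate=0.04, severe=0.01)
        joint = compute_burden([s1, s2], [p1, p2], params)
        split = compute_burden([s1], [p1], params) + compute_burden([s2], [p2], params)
        for channel, value in joint.as_dict().items():
            assert value == pytest.approx(split.component(channel), rel=1e-12)

    def test_homogeneous_in_births(self, params):
        base = compute_burden([_stratum(births=100.0)], [self.IDA], params)
        scaled = compute_burden([_stratum(births=300.0)], [self.IDA], params)
        for channel, value in scaled.as_dict().items():
            assert value == pytest.approx(3 * base.component(channel), rel=1e-12)

    def test_monotone_in_prevalence(self, params):
        worse = AnemiaPrevalence(none=0.7, mild=0.15, moderate=0.12, severe=0.03)
        lo = compute_burden([_stratum()], [self.IDA], params)
        hi = compute_burden([_stratum()], [worse], params)
        for channel in lo.as_dict():
            assert hi.component(channel) >= lo.component(channel) - 1e-12

    def test_totals_identity(self, params):
        result = compute_burden([_stratum()], [self.IDA], params)
        assert result.losses_total == pytest.approx(
            result.losses_cognitive + result.losses_mortality)
        assert result.dalys_total == pytest.approx(
            result.dalys_physical + result.dalys_cognitive + result.dalys_mortality)

    def test_stratum_mismatch_rejected(self, params):
        with pytest.raises(ValidationError, match="strata"):
            compute_burden([_stratum()], [], params)
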