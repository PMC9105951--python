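# Default model parameters. Epidemiological and economic coefficients whose
# published values are not available ship as documented stand-ins (see
# docs/methods.md); every value here is overridable.
anemia_cutoffs_gdl: [7.0, 10.0, 11.0]   # severe / moderate / mild upper bounds, WHO 6-59 mo
ida_share: 0.46                          # midpoint of the 0.25-0.67 literature envelope
dw_mild: 0.004
dw_moderate: 0.052
dw_severe: 0.149
dw_cognitive: 0.01
mortality_risk_severe: 0.008
cognitive_income_loss: 0.04              # fraction of lifetime earnings lost per IDA case
exposure_years: 1.5                      # anemia exposure in the 6-23 month window
discount_rate: 0.03
income_growth: 0.04                      # mean yearly income growth, previous decade
working_ages: [15.0, 65.0]
life_expectancy_years: 71.0
exchange_rate_idr_per_usd: 14582.0       # 2020 mean
national_wage_idr_per_year: 31900000.0
max_effect_gdl: 0.87                     # Hb gain ceiling of fortified cereals
effect_lag_months: 6.0                   # months of consumption to reach the ceiling
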