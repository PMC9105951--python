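"""Anemia severity prevalence from a hemoglobin distribution.

Builds the pooled Hb distribution of Indonesian children aged 6-23 months
(mean 10.5, sd 1.4 g/dL), classifies severity with the WHO cutoffs on
altitude-adjusted values, and prints the implied prevalence by severity.
"""

from idaburden import HbDistribution, adjust_for_altitude, prevalence_from_distribution

CUTOFFS = (7.0, 10.0, 11.0)  # severe / moderate / mild upper bounds, g/dL

dist = HbDistribution(mean=10.5, sd=1.4)
prev = prevalence_from_distribution(dist, CUTOFFS)

print("Pooled Hb ~ normal(10.5, 1.4) g/dL, WHO cutoffs 7/10/11")
for severity in ("none", "mild", "moderate", "severe"):
    print(f"  {severity:>8}: {100 * getattr(prev, severity):5.1f}%")
print(f"  any anemia: {100 * prev.any_anemia:.1f}%")

# a child measured at 11.2 g/dL living at 1500 m is anemic once adjusted
adjusted = adjust_for_altitude(11.2, altitude_m=1500)
print(f"\nMeasured 11.2 g/dL at 1500 m -> adjusted {adjusted:.1f} g/dL (mild anemia)")
# The severity fractions always sum to one; 'any anemia' is everyone below
# the mild cutoff on the altitude-adjusted scale.
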