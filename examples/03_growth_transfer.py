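"""Transfer published comparison-area growth to an adopter area's baseline.

Uses the published forecast counts for non-adopter areas of one rural-urban
class (baseline 4451.0 outlets in 2015) to derive cumulative growth rates,
then applies them to a hypothetical adopter area that had 120 outlets in its
zones at baseline.
"""

import pandas as pd

from zonecast import apply_growth, baseline_year, to_growth_schedule

forecasts = pd.DataFrame(
    [
        (2022, 6173.6, 5925.6, 6421.6),
        (2026, 6976.0, 6421.4, 7530.6),
        (2031, 7979.0, 7194.7, 8763.3),
    ],
    columns=["year", "mean", "lower95", "upper95"],
)

base_year = baseline_year(adoption_year=2017)
sched = to_growth_schedule(forecasts, baseline_count=4451.0, base_year=base_year)
print(f"baseline year: {base_year} (adoption 2017 minus two)")
print("cumulative growth rates (%):")
print((sched.rates.set_index('year') * 100).round(1).to_string())

proj = apply_growth(120.0, sched, area_id="adopter")
print("\nprojected outlet counts for an adopter with 120 baseline outlets:")
print(proj.counts.round(1).to_string(index=False))
# 2031 rate of 79.3% maps 120 outlets to ~215.1: the adopter is assumed to
# follow its class's business-as-usual trajectory absent intervention.
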