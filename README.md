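# zonecast

Local authorities in England can refuse planning permission to new hot-food
takeaways inside *management zones* — 400 m buffers around school sites. To
judge what such a policy may avert, one needs a counterfactual: how many
takeaways would appear inside those zones without intervention, and how much
of the population would be exposed to them? `zonecast` implements a two-stage
pipeline answering both questions, exercisable end to end on synthetic
geography with known ground truth.

**Stage 1 — forecasting.** Quarterly takeaway counts within management zones
of comparison (non-adopter) areas form a time series `y_t`. A non-seasonal
ARIMA(p, d, q) model, optionally with drift,

```
y'_t = c + Φ₁ y'_{t-1} + … + Φ_p y'_{t-p} + θ₁ ε_{t-1} + … + θ_q ε_{t-q} + ε_t
```

(`y'` the d-times differenced series) is selected by: KPSS tests for d,
Box-Cox if variance drifts, and an exact-maximum-likelihood grid over
p, q = 0…5 scored by AICc, with Ljung-Box residual checks and rolling-origin
cross-validation (RMSE, MASE) against an ETS benchmark. Forecast counts are
converted to cumulative growth rates anchored at a *baseline year* (adoption
year − 2) and transferred multiplicatively to an adopter area's own baseline
count.

**Stage 2 — exposure.** Overlapping school zones are re-cut into mutually
exclusive polygons stratified by takeaway density (quartic-kernel density
surface with a 2 km context belt, three natural-breaks classes, same-class
dissolve, centre-line overlap splitting). Each commuting sub-population
(origin OA i, destination OA j, mode m from census-style flow tables split by
LSOA mode shares) gets exposure domains: 1-mile home and work discs and a
buffered shortest network route (500 m automobile, 100 m active travel;
public transport contributes only 100 m-buffered walks to the nearest stop).
Exposure from zone k in domain p is

```
Exposure_ijmkp = population_ijm × count_k × area_intersected_ijmkp / area_k
Exposure_per_capita = Σ Exposure_ijmkp / population_total
```

with home exposure double-counted for people working from home or within
their home OA. Growth rates from stage 1 scale `count_k`, so per-capita
exposure projects forward by the same multiplier.

## Worked example

```
python examples/02_forecast_zone_counts.py
```

simulates a 41-quarter series with true drift 20 outlets/quarter and prints:

```
selected: ARIMA(0, 1, 0) with drift
drift estimate: 20.49 outlets/quarter (truth: 20)
AICc: 286.35; Ljung-Box p = 0.38 (no residual autocorrelation if large)

annual (Q2) forecasts with 95% intervals:
 year   mean  lower95  upper95
 2022 5324.7   5292.5   5356.9
 ...
 2031 6062.4   5960.5   6164.3
```

The selection recovered the generating model (a random walk with drift) and
its drift to within sampling error; intervals widen with the square root of
the horizon, as they must for that model. `examples/03_growth_transfer.py`
converts published comparison-area forecast counts (baseline 4451.0 in 2015)
into cumulative growth rates — 38.7% by 2022, 79.3% (95% CI 61.6–96.9%) by
2031 — and applies them to an adopter's baseline of 120 outlets, giving
215.1 (194.0–236.3) outlets by 2031. The other examples build exposure
spaces and run the full pipeline; `examples/05_full_pipeline.py` ends with a
byte-reproducibility manifest.

A thin CLI mirrors the stages: `zonecast simulate | zones | forecast |
growth | exposure | run` (see `zonecast --help`).

## Layout

- `src/zonecast/synth.py` — synthetic study-area generator (ground truth known)
- `src/zonecast/zones.py` — management zones, KDE, natural breaks, overlap splitting
- `src/zonecast/forecasting.py` — ARIMA selection, forecasting, CV, ETS benchmark
- `src/zonecast/_arma.py` — exact-likelihood ARMA engine (numba Kalman filter)
- `src/zonecast/growth.py` — growth-rate transfer to adopter areas
- `src/zonecast/exposure.py` — exposure domains and the exposure equation
- `src/zonecast/pipeline.py`, `cli.py`, `io.py` — driver, CLI, plain-text formats
- `docs/methods.md` — modelling assumptions, defaults, numerical choices
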