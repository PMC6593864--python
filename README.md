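# heatlag

Heat stress depresses milk yield and raises the somatic cell score (SCS) of
dairy cows, but not instantly: the exposure that matters most happened some
days before the milk was recorded. `heatlag` estimates **how long that lag
is** and **at what heat load the effect begins**, from monthly Dairy Herd
Improvement (DHI) test-day records joined to daily weather-station data.

It is written for quantitative geneticists and livestock epidemiologists
who work with test-day models, and ships a calibrated synthetic-data
generator so that the whole pipeline is testable end to end by parameter
recovery.

## The model

Daily heat load is the temperature–humidity index computed from mean daily
temperature *t* (°C) and mean daily relative humidity *rh* (%):

    THI = 1.8 t + 32 − (0.55 − 0.0055 rh)(1.8 t − 26)

(at *rh* = 100 the index equals the temperature in °F). Somatic cell counts
are scored as `SCS = log2(SCC / 100,000) + 3`.

For each candidate lag *d* ∈ {0, …, 14} days, the test-day response is fitted
by the categorical fixed-effects model

    y = herd + calving_year + month + age_group + DIM_class + THI_class(d) + e

where `DIM_class` is one class per day in milk (6–305, 300 classes) and
`THI_class(d)` is the integer-binned THI at the herd's station *d* days
before the test day. Herds are split at random into *k* = 5 subsets (herds
kept whole) and each subset is fitted separately; the lag minimizing the
mean AIC across subsets — compared against a *basic* model without the THI
term — is selected.

The heat-stress threshold is then estimated from the least-squares means
(LSMs) of the THI classes at the selected lag, pooled across subsets and
restricted to well-populated classes, with a segmented regression
constrained to zero slope below the breakpoint BP:

    y* = c + e                 for x ≤ BP
    y* = c + b (x − BP) + e    for x > BP

BP is profiled on a 0.1-unit grid with (c, b) solved exactly at each
candidate.

## Worked example

```python
import heatlag as hl

scen = hl.default_scenario(seed=7)                 # ~210,000 records
testday, weather, mapping, truth = hl.simulate_scenario(scen)

scan, pooled, filtered, bp, min_count = hl.analyze_trait(
    testday, weather, mapping, trait="milk", seed=11)

print("selected lag:", scan.selected_lag, "days; truth:",
      truth["milk"]["true_lag_days"])
print("breakpoint:", round(bp.bp, 1), "THI; slope above:", round(bp.b, 3),
      "kg/day per THI; truth:", truth["milk"]["bp"])
```

prints

```
selected lag: 3 days; truth: 3
breakpoint: 70.8 THI; slope above: -0.296 kg/day per THI; truth: 70.4
```

i.e. the scan recovers the generating 3-day lag exactly, and the segmented
fit places the milk-yield threshold within half a THI unit of the
generating breakpoint, with the expected negative slope (~0.3 kg/day lost
per THI unit above threshold). Running the same analysis with
`trait="scs"` recovers the longer SCS lag (8 days) and its threshold
(68.5), with a positive slope.

The same analysis is available from the shell:

```sh
heatlag simulate --scenario default --seed 7 --out data/
heatlag lagscan --testday data/testday.csv --weather data/weather.csv \
    --map data/herd_station.csv --trait milk --seed 11 --out lagscan.csv
heatlag run --config config.yaml     # full pipeline with report.md
```

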