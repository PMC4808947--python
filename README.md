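# heatmort

District-level analysis of heat-related cardiovascular mortality:

- **synthetic data** — gridded daily temperatures (seasonal cycle + shared
  AR(1) anomaly + altitude lapse), grid→district membership, district death
  counts by age band with a known acute heat effect and an optional
  frail-pool depletion mechanism that produces mortality displacement
  (harvesting), census-like district covariates, and a municipality table
  for the rurality criterion;
- **temperature aggregation** — population-weighted district daily means,
  unweighted district altitudes, summer mean temperature;
- **rate standardization** — directly standardized daily mortality rates
  against a standard-population weight table;
- **baseline model** — one location-stratified quasi-Poisson model over the
  pooled panel: natural cubic spline on time (7 df per year, 112 df over a
  16-year period) plus day-of-week and district categoricals (a Gaussian
  identity option is exposed);
- **excess statistics** — hot days (strict exceedance of the summer 90th
  percentile by linear-interpolated order statistics), percent relative
  deviations from baseline, per-district DevCVD, Monte-Carlo 90 % null
  bounds from resampled summer days;
- **ecological regression** — SES index (negated sum of deprivation
  z-scores), OECD rurality criterion, Spearman matrix, VIF screening,
  bidirectional stepwise AIC with an F-significance screen, Global Moran's
  I with permutation p-values, SES-stratified regressions;
- **hot-spell lag analysis** — four SES × urbanization district groups,
  group-averaged series with a refitted baseline, hot spells (≥ 2
  consecutive hot days), lag profiles D−2..D+14 with 90 %/95 % Monte-Carlo
  bounds, and cumulative sums ΣD+0..D+3 vs ΣD+4..D+14 quantifying
  displacement.

## CLI

Each stage reads/writes UTF-8 CSV so stages can run independently:

```bash
heatmort simulate --preset acute_only --seed 1 --out-dir data/
heatmort aggregate --grid data/grid_temps.csv --cells data/cells.csv --out data/district_temps.csv
heatmort standardize --mortality data/mortality.csv --standard data/standard_population.csv --out data/rates.csv
heatmort baseline --rates data/rates.csv --out data/baseline.csv
heatmort excess --data-dir data/ --seed 1 --out out/classification.csv
heatmort spatial --data-dir data/ --seed 1 --out-dir out/
heatmort spells --data-dir data/ --seed 1 --out-dir out/
heatmort report --preset rural_displacement --seed 1 --out-dir out/
```

Scenario presets: `null`, `acute_only`, `urban_no_displacement`,
`rural_displacement`. Configuration is a flat YAML file (see
`heatmort.config.StudyConfig` for keys and defaults); CLI flags override
file values and every run logs the fully resolved configuration and seed.

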