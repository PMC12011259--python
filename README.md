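# forestcarbon

A toolkit for biomass-based forest carbon-sink measurement:

- **inventory_io** — read, splice and clean forest inventory tally tables
  (species-name normalization, outlier screening against a reference
  allometry, organ-mass imputation, dual-entry table diff).
- **sampling_design** — number of monitoring plots needed to hit an
  absolute error bound at a chosen reliability index, finite-population
  adjustment, and optimal (Neyman-style) allocation across carbon strata.
- **biomass_models** — allometric power-law fitting (M = a·D^b, log-log
  least squares) and a small feed-forward network on DBH/height/age/region,
  root–shoot conversion, and R²/MAE/RMSE/MSE evaluation.
- **carbon_accounting** — per-pool (tree/shrub × above/belowground) carbon
  stocks, year-over-year stock changes via the 44/12 operator, GHG
  emissions, leakage and baseline terms, and the project's net CO₂e sink.
- **stand_metrics** — per-species volume/count subtotals, survival ratios
  and stand volume densities.
- **validation** — absolute/relative prediction-error statistics against
  a packaged per-age validation table for Chinese fir.
- **synthetic_data** — seeded generators for even-aged stands and
  multi-year project ledgers with analytically known net sinks.

Reference tables (validation table, plot volume tables, plot summaries)
ship with the package as CSV fixtures under `forestcarbon/data/`.

## CLI

All subcommands emit JSON; `--config file.yaml` can pre-set any flag.

```bash
# plot count + allocation from a strata CSV (stratum_id,area_weight,stock_sd)
forestcarbon sample-size --strata strata.csv --area 100 --plot-area 0.08 \
    --tval 1.645 --error 5

forestcarbon allocate --strata strata.csv --n 30

# fit M = a*D^b on a tally CSV with dbh_cm and biomass_kg columns
forestcarbon biomass fit --data tally.csv
forestcarbon biomass predict --data tally.csv --a 0.1 --b 2.4

# per-year net sink from a pool-stock ledger
forestcarbon account --ledger ledger.csv --ghg ghg.csv --baseline cleared

# prediction-error statistics (defaults to the packaged validation table)
forestcarbon validate
forestcarbon validate --table table2.csv

forestcarbon stand-stats --total 36.00 --surviving 30.30 --plot-area 0.8

forestcarbon simulate --n-trees 200 --age 12 --seed 42 --out inventory.csv
```

Input tables are UTF-8 CSV with a header row. Sources kept in Excel
should be exported to CSV first (e.g. `File → Save As → CSV` or
`ssconvert`); the core deliberately does not parse binary spreadsheets.

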