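# File schemas

All tabular interchange is plain CSV; a dataset directory written by
`ieg.io_config.write_dataset` (or by `analysis/01_simulate_network.py`)
contains:

| file | columns | notes |
|---|---|---|
| `sites.csv` | `site_id, x, y, clump` | coordinates in planar km; `clump` is generator metadata. Geographic inputs instead carry `lon, lat` and are projected at load (`coordinate_mode="geographic"`). |
| `annual.csv` | `site_id, year, pollutant, value, sqrt_value` | `value` in native units (ppb, ppm, µg/m³); `sqrt_value` = √value. Optional `included` / `exclusion_reason` columns from the aggregation stage are honoured at load. |
| `covariates.csv` | `site_id, V0000, V0001, …` | one column per geographic variable, no missing values at retained sites. |
| `categories.csv` | `variable, category` | category per variable (traffic, population, urban/rural land use, elevation, vegetation, imperviousness, industrial emissions, position, source, satellite). |
| `truth.json` | — | synthetic ground truth: `beta`, `informative_idx`, `cov_params` (range km, partial sill, nugget), `seed`. |
| hourly series | `timestamp, value` | ISO timestamps; at most one row per hour. |

`load_tables` inner-joins on `site_id`, drops (and counts) sites missing
covariates or measurements, and hard-errors on duplicated ids, non-numeric
coordinates or missing covariate values.  Exclusion reports from the
variable screen are written as `variable, reason` CSVs.  Fitted
universal-kriging models serialise to a single JSON bundle
(`save_uk_model` / `load_uk_model`).  Run configuration is YAML with the
fields of `ieg.io_config.RunConfig`; unknown keys are rejected and defaults
are 2 / 3 PLS components for conventional / clustered CV, the standard
subset-size sweep, and buffer radii 50/100/200/300 km.
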