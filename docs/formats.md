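# FORMATS

All files are UTF-8, comma-separated, dot decimal, header mandatory.
Lines starting with `#` are comments; in files that carry metadata they
hold `key: value` pairs. Writers are deterministic (fixed column order
and formatting).

## Conversion–time series

Consumed by `fit-apparent`, `orders`; emitted by `simulate`.

```
# temperature_C: 30
# w_h2so4_percent: 94
# c_io0_M: 0.5
# c_hno3_0_M: 2.2
time_s,x_io
60,0.0908
120,0.1702
180,0.2403
```

- `time_s` strictly increasing, ≥ 0. With `time_unit: min` in the run
  config (or `time_min` column) values are minutes and converted on
  ingest.
- `x_io` in [0, 1). Violations are reported with row and column.
- The four condition keys are required (header block or sidecar
  override). Extra keys are preserved as series metadata.

## Apparent-rate table

Emitted by `fit-apparent`; consumed by `fit-intrinsic`, `predict`,
`surface`, `optimize`.

```
temperature_C,w_h2so4_percent,k_L_per_mol_s,r2,intercept
30,88,0.0002937,1.000000,0.000000
```

`k_L_per_mol_s` must be positive; it is written to 4 significant
figures. Internal values are plain SI (any ×10² display convention is
presentation only).

## Nitronium table

Consumed by `fit-intrinsic` and friends; emitted by `simulate`
(synthetic, noise-free by default).

```
temperature_C,w_h2so4_percent,lg_ratio
23,88,-2.41
23,90,-2.05
40,88,-2.55
```

≥ 2 distinct mass fractions per temperature and ≥ 2 temperatures.

## Intrinsic report

Emitted by `fit-intrinsic --out PREFIX` as `PREFIX.csv` + `PREFIX.json`.

```
temperature_C,n,lg_k0,r2
30,1.0764,11.3549,1.000000
# ea_kJ_per_mol: 192.69
# ln_a: 102.60
```

`n` and `lg_k0` to 4 decimals, Ea to 2 decimals. The JSON mirror holds
the same content at full precision plus the gas constant used.

## Validation pairs

Consumed by `validate`.

```
predicted,observed
0.90,0.86
```

Conversions as fractions; the report is in percentage points, pairing
is positional.

## Nitronium model document (JSON)

`NitroniumModel.to_json()`: stage-1 and stage-2 line coefficients with
per-line R² and spans, plus calibration ranges — sufficient to
re-evaluate the surface without the input table.

## Run config (YAML, flat key-value)

Every key optional; unknown keys are rejected. Defaults in parentheses.

```
gas_constant: 8.314        # J/(mol K)
density_table: null        # path to a replacement density CSV
time_unit: s               # or: min
delta_r2: 0.005            # order-selection ambiguity threshold
strict: false              # drop nitronium-extrapolated rows in fits
soft_t_min_C: 30           # model-construction window
soft_t_max_C: 40
soft_w_min: 88
soft_w_max: 98
soft_time_max_min: 4.7
hard_t_min_C: 0            # refuse beyond these
hard_t_max_C: 45
hard_w_min: 80
hard_w_max: 100
hard_time_max_min: 15
t_step_s: 30               # optimizer grid steps
temp_step_C: 2.5
w_step: 1
```

## Density table

`mass_fraction_percent,density_g_per_ml`, sorted, ≥ 2 rows; the
bundled file covers 80–100 wt % in 1-point steps.

## Exit codes

0 success · 2 schema/validation error · 3 fit failure · 4 envelope
violation.
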