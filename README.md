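# concindex

Concentration-index estimation for aggregated population-register data,
with Monte Carlo confidence intervals.

The concentration index (C) summarizes socioeconomic inequality in a health
outcome across ordered socioeconomic groups (twice the area between the
diagonal and the concentration curve; 0 under complete equality, negative
when the outcome is concentrated among the disadvantaged). For
total-population register data the usual survey-based standard errors are
the wrong tool: there is no sampling error, and uncertainty comes from
registration and coding. This package implements

- the index itself, computed both by the arithmetic formula and by the
  computationally equivalent weighted-least-squares regression, together
  with direct age-standardization of group rates and the concentration
  curve (`concindex.core_index`);
- two analytic reference intervals: the conventional WLS slope interval
  (REG) and a serial-correlation-corrected variance interval (KWV)
  (`concindex.interval_regression`);
- five Monte Carlo interval procedures that resimulate the outcome —
  the regression's dependent variable (MC), the age-standardized rates
  (MC_RATE), or the raw cell counts under binomial (BIN), Poisson (POIS)
  or multinomial (MN) models — and read off empirical percentile intervals
  (`concindex.interval_montecarlo`), plus an empirical cross-year variance
  check for panels of rates;
- a machine-readable amenable-mortality cause list (ICD-10 code patterns
  with age windows) and a classifier over (code, age) pairs
  (`concindex.amenable_classifier`);
- a synthetic register generator with a controllable true index, including
  a calibrated register-scale preset, so everything is testable without
  access to real register data (`concindex.synthetic_register`);
- CSV readers/writers and a CLI (`concindex.cli_io`).

## Input formats

Counts are long-format CSV with header
`age_group,seg,seg_order,deaths,person_years`. `seg_order` (integer 1..G,
1 = least advantaged) declares the socioeconomic ordering explicitly;
it is never inferred from labels, because a flipped ordering silently
negates the index. The table must be dense: every (age group, seg) cell
present, integer deaths, positive person-years.

The standard population is a CSV `age_group,weight`. Weights are
normalized at load time to sum to exactly 100,000 (so standardized rates
read as events per 100,000 person-years) regardless of the input scale.
A packaged illustrative European-style vector for ages 1–74 is used when
no file is given; supply your own weights for real analyses.

## CLI

```sh
# synthesize a register-like table (calibrated preset, ~2,100 deaths/year)
concindex simulate-data --preset finland-1996-men --seed 1 \
    --out table.csv --stdpop-out stdpop.csv

# point estimate by both estimators
concindex compute --counts table.csv --stdpop stdpop.csv

# one interval method
concindex ci --counts table.csv --stdpop stdpop.csv \
    --method bin --reps 10000 --seed 1

# all seven methods side by side
concindex compare --counts table.csv --stdpop stdpop.csv \
    --methods all --reps 10000 --seed 1 --out compare.csv

# amenable-mortality classification
concindex classify --icd I63.9 --age 60
```

Methods: `reg`, `kwv` (analytic), `mc`, `mc-rate`, `bin`, `pois`, `mn`
(simulation, percentile intervals, default 10,000 replicates). In
`compare`, each method draws from its own RNG substream derived from the
master seed, so results per method are stable under adding/removing
other methods.

Notes on the analytic methods: the KWV variance estimator is defined for
samples of n observations; no natural n exists for register summaries, so
the default here treats each group summary as one observation (`--kwv-n`
overrides this). Expect REG/KWV to be conservative (wider) relative to the
simulation intervals on register-scale data.

## Python API

```python
import numpy as np
from concindex import (
    SimulationConfig, build_seg_profile, concentration_index_formula,
    preset_config, generate_table, run_interval,
)
from concindex.synthetic_register import default_standard_population

res = generate_table(preset_config("finland-1996-men"), np.random.default_rng(1))
stdpop = default_standard_population()
profile = build_seg_profile(res.table, stdpop)
print(concentration_index_formula(profile).C, "true:", res.true_C)

iv = run_interval(res.table, stdpop,
                  SimulationConfig(method="BIN", n_replicates=10_000, seed=1))
print(iv.C, (iv.lower, iv.upper), iv.length)
```

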