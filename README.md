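# shiftuse

Time-use extraction and isotemporal substitution modelling for
night-shift-worker accelerometry.

The package turns epoch-level, pre-scored accelerometer records plus a
work roster into per-day-type (workday vs leisure-day) minutes of
sedentary behaviour (SB), light physical activity (LPA),
moderate-to-vigorous physical activity (MVPA) and main sleep, then
estimates associations with cardiovascular risk factors using
single-factor and isotemporal substitution regression models. A
synthetic-cohort generator with known ground truth (shift calendars,
minute-grid epoch streams, exclusion rosters, planted outcome effects)
makes every stage testable without external data.

## Modules

| module | what it does |
| --- | --- |
| `shiftuse.timeuse` | METs cut-point classification (SB ≤ 1.5, LPA 1.5–3.0, MVPA ≥ 3.0), 24 h day windows from the roster, per-day aggregation, per-participant day-type means, staged exclusion cascade |
| `shiftuse.models` | OLS single-factor and isotemporal models per (outcome × day type × reference), standardized and per-30-min effects with Wald 95 % CIs, VIF diagnostics, paired Wilcoxon day-type comparison, arrow-direction summaries |
| `shiftuse.synth` | cohort plans (defaults follow the study's printed descriptive parameters), alternating night-shift calendars, 1-min epoch grids, status rosters, outcomes from a configurable linear model with planted reallocation effects |
| `shiftuse.cli` | `shiftuse simulate | extract | fit | report` with strict YAML config and JSON run manifests |
| `shiftuse.io` | the plain-CSV dialects for epochs, rosters, status tables and participant tables |

## CLI

```bash
# simulate a 66-participant cohort, one week of 1-min epochs
shiftuse simulate --seed 7 --out-dir run/ --n-participants 66 --n-days 7

# epochs + roster (+ status table) -> per-day / per-participant time use
shiftuse extract --epochs run/epochs.csv --roster run/roster.csv \
    --status run/status.csv --out-dir run/

# fit the 11-outcome x day-type x reference model grids
shiftuse fit --participants run/participants.csv --out-dir run/

# descriptive table, effect listing, arrow summary
shiftuse report --estimates run/estimates.csv \
    --comparison run/daytype_comparison.csv --out-dir run/
```

Each stage writes a `manifest_<stage>.json` with the config snapshot,
input digests and timings. A YAML config (`--config`) can override any
plan or model setting; unknown keys are rejected.

## Library quick start

```python
import shiftuse as su
from shiftuse import synth

plan = su.default_plan()
cohort = synth.generate_cohort(plan, seed=1, n_participants=66)
days, participants = su.extract_participants(cohort.epochs, cohort.roster)

grid = su.run_analysis_grid(cohort.participants)
sig = grid[grid.significant & (grid.family == "isotemporal")]
```

## Conventions

- Timezone-naive local clock; half-open intervals `[start, start + duration)`;
  day windows are 24 h blocks anchored at roster arrivals (leisure blocks
  tile the gaps).
- Only main sleep counts as the sleep behaviour; non-main sleep and
  non-wear pass through and never enter SB or sleep.
- Log-flagged outcomes (TG, AST, ALT, γGPT) are base-10 log-transformed
  before modelling; both fully standardized and raw per-Δ-minute effects
  are reported.
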