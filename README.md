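# edflow

Discrete-event simulation of emergency-department (ED) patient flow,
with full-factorial experimentation and interaction-effects analysis
for staffing and bed-capacity decisions.

Patients arrive by a non-homogeneous Poisson process and move through
registration and triage (parallel branches), bed placement, physician
consultation, nurse documentation, optional imaging/lab tests,
reassessment and a discharge process, competing for seven resource
pools across an adult and a pediatric zone. The package covers the full
loop: simulate → validate against reference KPIs → design-of-experiments
→ regression/ANOVA/effect ranking.

## Components

| Module | What it does |
| --- | --- |
| `edflow.distributions` | Parses service-time strings (`TRI(2, 3, 5)`, `1 + 2 * Gamma(0.1, 2.5, 2.5)`, …) into sampleable laws with closed-form moments and seeded, named substreams |
| `edflow.des` | Minimal process-based event engine (event heap, generators, FIFO resources) |
| `edflow.simulator` | The two-zone ED pathway; emits per-patient milestone logs |
| `edflow.kpi` | AtT / AtD / LOS KPIs and percentage-difference validation |
| `edflow.doe` | Full-factorial designs over resource capacities, run with common random numbers |
| `edflow.effects` | Interaction regressions, per-term F tests, standardized-effect (Pareto) / main-effect / interaction summaries |
| `edflow.calibration` | Budgeted Nelder–Mead parameter tuning against reference KPIs; Q-Q / P-P diagnostics |
| `edflow.synth` | Synthetic timestamp logs and 24-hour arrival profiles with known ground truth |

## CLI

```bash
# simulate a scenario (YAML config; defaults used when omitted)
edflow simulate --config scenario.yaml --out runs/ --seed 42 --replications 10

# validate simulated KPIs against reference means
edflow validate --sim runs/ --reference reference_kpis.csv --out table.csv

# full-factorial experiment over capacities (per-zone 3-factor default)
edflow doe --config scenario.yaml --zone adult --replications 10 --out responses.csv

# regression + ANOVA + Pareto of effects
edflow analyze --responses responses.csv --response LOS --out-prefix out/adult_los

# tune free parameters against reference KPIs
edflow calibrate --config scenario.yaml --free params.yaml \
    --target reference_kpis.csv --budget 200 --out calib.json

# synthetic data
edflow synth log --n 500 --seed 7 --out log.csv --truth truth.json
edflow synth profile --total 240 --peak 11 --ratio 3 --out profile.csv
```

Event logs are CSV with the eight-column header
`Arrive,Reg,Triage,Bed,Doc,Discharge,Room,Discharge status` in one of
three timestamp dialects (`minutes`, lossless, the default for
analysis; `table`, the minute-resolution `MM/DD H:MM` style; `iso`).
The reference-KPI file schema is `variable,real_minutes`.

## Notes

- Identical `(seed, stream id)` pairs reproduce identical variate
  sequences; scenarios sharing a seed see common random numbers (the
  arrival process is generated by inversion so that arrival times
  co-vary smoothly as rates change).
- Unprinted quantities in the source material (arrival-rate magnitudes,
  routing probabilities, physician counts, zone mix) are documented,
  calibratable configuration defaults — see `edflow/config.py`.
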