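# ventinv

Inverse estimation of mechanical-ventilator settings from desired patient
observations.  A forward neural surrogate (8 ventilator settings and
demographics → 7 patient responses) is inverted by a **graded particle swarm
optimizer** (GPSO) in a feedback loop: the swarm searches settings-space to
minimize the squared normalized mismatch between surrogate predictions and
the target observation, with the patient's age and weight frozen and all
settings clamped to cohort bounds.  Because the search is stochastic, a
campaign of repeated trials over an ensemble of surrogates produces a
*range* of plausible settings (min / max / mean / sd per parameter) rather
than a single point estimate.

## Package layout

| Module | Role |
| --- | --- |
| `ventinv.gpso` | Graded swarm optimizer: equal-size groups, per-group leaders and a universal leader; classic PSO (`pso_optimize`) kept as an independent reference implementation. |
| `ventinv.surrogate` | Training, scoring, ranking and JSON persistence of the forward networks (tanh MLP, hidden layers 8-16-14-7, min-max normalization, total error = SSE over train+validation+test splits). |
| `ventinv.dataprep` | Pruning: deterministic compliance fills (`Cdyn = Vti/(PIP−PEEP)`), per-field neural imputation clamped to observed bounds, cohort segregation. |
| `ventinv.inverse` | The inversion engine: fitness (½·Σ squared normalized residuals), seeded trials, campaigns over trials × ensemble members, report aggregation. |
| `ventinv.synthetic` | Ground-truth ventilated-patient simulator: smooth monotone response map with the compliance identity exact, multiplicative noise, missing-at-random cells, and inversion fixtures with known answers. |
| `ventinv.pipeline` / `ventinv.cli` | File-staged orchestration (simulate → prune → train → invert → report) with `desk`, `table2` and `text` scale profiles. |

## CLI

```bash
# whole flow at workstation scale into ./artifacts
ventinv run-all --profile desk --seed 0 --out artifacts

# or stage by stage
ventinv simulate --seed 0 --out artifacts
ventinv prune    --seed 0 --out artifacts
ventinv train    --seed 0 --out artifacts
ventinv invert   --seed 0 --out artifacts
ventinv report   --seed 0 --out artifacts

# invert your own targets (CSV: 7 observation columns + age + weight per row)
ventinv invert --targets targets.csv --ensemble artifacts/models --out artifacts
```

All options can come from a YAML config (`--config pipeline.yaml`); flags
override the file.  Profiles: `desk` (population 200, 10 groups, 20
candidate networks keeping 3, 10 trials), `table2` and `text` (population
2000, 50 groups, 200 candidates keeping 10, 100 trials; they differ in the
termination rule: 100 iterations / tolerance 0.01 vs 1000 iterations /
tolerance 0.0001).  Every JSON artifact is stamped with the seed and a
config hash; identical seed + config reproduce byte-identical reports.

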