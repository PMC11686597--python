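# epicua

A Markov cohort cost-utility model for add-on cannabidiol (CBD) versus usual
care alone in two severe, treatment-refractory epileptic encephalopathies:
Lennox-Gastaut syndrome (LGS) and Dravet syndrome (DS).

## Who this is for

Health-economic modellers and methods researchers who want a fully tested,
reproducible implementation of a seizure-frequency state-transition
cost-utility analysis: the cohort engine, discounted cost/QALY accrual,
incremental economics with dominance handling, one-way and probabilistic
sensitivity analysis, and a scenario battery — all driven by a synthetic-input
generator, because the trial-derived per-cycle occupancy data behind the
original analysis are confidential.

## The model in brief

Patients occupy one of six states: seizure-free; {low, high} seizure
frequency × {few, many} seizure-free days (SFD); dead. LGS bands at 55 drop
seizures and 15 SFD per month, DS at 12 convulsive seizures and 18 SFD; the
structure is otherwise identical. Over 360 three-month cycles (90 years),
per-cycle occupancy profiles place the surviving on-treatment cohort across
the alive states (cycle 1 trial effect, cycles 2–9 extension data, frozen
thereafter for CBD; the usual-care arm keeps its cycle-1 placebo-effect
distribution for life). Background life-table mortality plus SUDEP/non-SUDEP
excess hazards remove mass to death; CBD-arm patients discontinue on a
cycle-banded schedule with a months-6/12/24 stopping rule for
non-responders (<30% seizure reduction).

Per arm, discounted totals accumulate as

- QALYs:  Σₖ (occupancyₖ · u) · ¼ · (1+0.015)^(−k/4)
- Costs:  drug + ASMs + care hours + resource use + adverse events + travel,
  each · (1+0.04)^(−k/4)

and the comparison reports ΔC, ΔQ, the ICER ΔC/ΔQ (or a dominance verdict),
and net monetary benefit `NMB = λ·ΔQ − ΔC` at λ = EUR 80 000/QALY.

With the *published* per-arm totals as inputs, the incremental stage
reproduces the printed results: LGS ΔC = EUR 28 338, ΔQ = 1.318 (ICER below
the threshold); DS dominance (cost saving with a QALY gain). The synthetic
base case is **not** calibrated to those totals — see
[docs/methods.md](docs/methods.md).

## Worked example

```bash
$ epicua report --condition LGS --seed 1 --out report
LGS: dCost 24,244, dQALY 0.521, ICER 46,572; outputs in report/
```

Under the default synthetic inputs (seed 1), add-on CBD costs an extra
EUR 24 244 per patient over a lifetime, gains 0.521 QALYs, and so buys a
QALY at EUR 46 572 — cost-effective against the EUR 80 000 threshold. The
output directory holds both arms' cycle-by-cycle traces (CSV), the
incremental record (JSON) and a manifest with the config hash, seed and
every FICTIONAL placeholder parameter used.

The same from Python:

```python
from epicua import default_config, run_condition

res = run_condition(default_config("DS"), seed=1)
print(res.cea.verdict, round(res.cea.delta_cost), round(res.cea.delta_qaly, 3))
# ICER 10227 0.111
```

Other commands: `epicua generate` (write the synthetic input bundle),
`run` (one arm's trace), `evaluate` (itemized costs/QALYs per arm),
`compare`, `owsa` (tornado CSV), `psa --draws 1000` (draw matrix + CEAC),
`scenarios --set all`, and `schema` (JSON schema for config files).
Configs are YAML/JSON validated against the shipped schema
(`src/epicua/config.schema.json`).

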