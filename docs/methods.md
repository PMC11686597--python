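# Methods

## The model

`epicua` implements a cohort-based Markov state-transition model for the
cost-utility comparison of add-on cannabidiol (CBD) plus usual care versus
usual care alone in two treatment-refractory epileptic encephalopathies,
Lennox-Gastaut syndrome (LGS) and Dravet syndrome (DS).

The state space has six mutually exclusive compartments: seizure-free; a
low-frequency and a high-frequency seizure state, each split into two
sub-states by the number of seizure-free days (SFD) per month; and death
(absorbing). The structure is identical for LGS and DS; only the banding
thresholds differ — 55 drop seizures and 15 SFD per month for LGS, 12
convulsive seizures and 18 SFD for DS. The seizure-free compartment carries
no SFD sub-split: the split is undefined at zero seizures, and the published
inputs assign it a single utility and a single care-hours row.

Cycles are 3 months (365.25/4 days) over a 90-year (360-cycle) horizon.
Costs are discounted at 4.0% per annum and QALYs at 1.5%, per Dutch economic
evaluation guidance; the willingness-to-pay threshold is EUR 80 000/QALY.

### Occupancy rather than transition matrices

The published analysis assigns cohort state membership per cycle from trial
patient-level data rather than estimating a stationary transition matrix:
cycle 1 from the randomized trials, cycles 2–9 from the open-label
extension, and frozen occupancy thereafter for the CBD arm; the usual-care
arm keeps its cycle-1 (placebo-effect) distribution for life. The engine
therefore consumes *occupancy profiles* — per-cycle conditional
distributions over the alive states — and redistributes the surviving
on-treatment mass accordingly each cycle.

Because those trial data are confidential, the profiles here are synthetic
(see below). Nothing in the package is calibrated to reproduce the published
euro or QALY totals; the published per-arm totals enter only as *inputs* to
the incremental-economics stage, where the printed increments
(ΔC = EUR 28 338, ΔQ = 1.318 for LGS; dominance for DS) are arithmetic
consequences.

### Within-cycle ordering and related choices

- Each cycle: redistribute surviving alive mass per the profile → apply
  mortality per state → record occupancy → apply discontinuation (effective
  from the next cycle). The ordering is a modelling choice (the source
  material does not state one) and is covered by the individual-level
  oracle, which uses the same order.
- No half-cycle correction in the base case; payoffs accrue on full-cycle
  occupancy. A `half_cycle_correction` flag applies trapezoid weights.
- A single mean-age clock per arm advances 0.25 years per cycle from the
  baseline mean age (13.2 y LGS, 11.5 y DS); the model does not re-weight
  the age distribution after differential mortality.
- Discontinued patients adopt the usual-care occupancy distribution from the
  next cycle (`discontinuation_behaviour="revert"`, the default, matching
  the convention that dropouts revert to comparator effectiveness); a
  `"retain"` mode keeps the mass-weighted distribution held at
  discontinuation instead.

### Mortality

Background mortality comes from an annual life table; the epilepsy excess
(SUDEP plus non-SUDEP) is added on the hazard scale and the combined hazard
converted to a 3-month probability: `1 − exp(−(−ln(1−q) + h_excess)/4)`.
In the base case mortality is equal across alive states; the risk-ratio
scenario multiplies the excess component by 0.71 for seizure-free patients.
The same excess rates are used for LGS and DS. Ages beyond the table use the
terminal annual probability.

### Discontinuation and the stopping rule

Applied to the CBD arm only (patients do not discontinue from usual care):
cycle 1 an adverse-event-driven short-term rate; cycles 2–9 an all-cause
per-cycle rate; cycles 10+ a constant 4.17% per cycle. The stopping rule
removes, at months 6, 12 and 24 (cycles 2, 4, 8), a one-off fraction
`stop_fraction × (1 − responder_fraction)` of remaining patients, where
responders are those with ≥30% seizure reduction. The 10%-long-term
scenario applies its rate only to the on-treatment mass occupying the four
seizure states. The lag scenario (`lag_cycles = 2`) keeps drug cost, at
usual-care effectiveness, for two further cycles after loss of effect.

### Costs and QALYs

QALYs: occupancy · state utilities × 0.25 years per cycle, discounted.
Utilities come from a time-trade-off vignette study and include zero and
negative values (worst LGS state −0.037); a cohort pinned there accrues
negative QALYs by construction. A serious-adverse-event disutility of −0.12
is applied for one cycle in the base case (the 9-cycle variant is a
scenario), weighted by the arm's per-cycle SAE probability. The caregiver
scenario subtracts `n_caregivers ×` a per-caregiver decrement from the alive
mass; the decrement magnitude is a FICTIONAL placeholder (no published
value).

Costs, itemized and linear in every unit cost: drug acquisition
(weight × 12 mg/kg/day × cycle days × price/mg over the drug-paying mass),
background antiseizure medications (both arms; clobazam at 100% usage),
family care at the EUR 14.95/h replacement cost (societal perspective only),
professional care at EUR 53.40/h, healthcare resource use (emergency
department and nurse visits, hospitalization with a general-ward/ICU mix,
institutionalization), adverse events (cycles 1–9 only), and travel per
visit (societal only). Administration/monitoring costs and productivity
losses are excluded by design. The healthcare perspective zeroes family care
and travel. Dosing weight mixes the four age-band mean weights by their
baseline proportions, with each band's midpoint age advancing along the
cycle clock so children grow into heavier bands and finally the adult band.

Expected lifetime event counts multiply state occupancy by per-state
per-cycle event probabilities and sum over the horizon.

### Incremental economics

ΔC and ΔQ between arms give either an ICER (ΔC/ΔQ), a DOMINATING verdict
(ΔC < 0 < ΔQ), a DOMINATED verdict (ΔC > 0 > ΔQ), or — when either delta is
exactly zero — a BOUNDARY verdict rather than a forced quadrant. ICERs are
carried unrounded internally; rounding is presentation-only. Net monetary
benefit is `WTP × ΔQ − ΔC`.

## Sensitivity analysis

**One-way (tornado).** Each parameter is varied alone to its lower and upper
bound (mean ± 1.96 SE where a published SE exists, otherwise ±20% of the
mean) with a full model re-run per bound; synthetic inputs are regenerated
under the same seed so only the varied parameter moves. Bars are ordered by
ICER range width, or by net-monetary-benefit range when the base case is
dominance-prone (the ICER is ill-behaved across quadrants).

**Probabilistic.** Every uncertain parameter is redrawn per simulation from
its assigned family: beta (method of moments) for probabilities and bounded
utilities, gamma for costs and nonnegative quantities, normal for the mean
age, truncated normal on [−1, 1] for utilities whose confidence interval
crosses zero (a plain beta cannot represent negative utilities), and
Dirichlet draws around the per-cycle occupancy distributions (configurable
concentration, default 500) for transition uncertainty. Whether occupancy is
redrawn is toggleable; the default redraws it. Distribution parameters are
validated before any draw. Evaluations are memoized on a fingerprint of the
drawn inputs, so degenerate (zero-variance) analyses cost a single model
run. The acceptability curve is the fraction of draws with positive net
benefit at each willingness-to-pay.

**Scenarios.** A battery of ~25 named variants mirrors the published
scenario table: 2023 price year, healthcare perspective, both arms frozen
after cycle 1, alternative banding thresholds, non-maintained treatment
effect, entry at age 2, 20- and 30-year horizons, two caregivers,
alternative utility sets, mortality risk ratio 0.71, 50/50 ICU split, 10%
long-term discontinuation in seizure states, 6-month lag, adverse-event
disutility/cost ×2 and ×3, 9-cycle disutility, swapped utility sources,
literature resource use, equalized care hours, equalized
institutionalization, and (DS only) adult weight set to the 12–17-year
band.

## The synthetic-data generator

The generator emulates the *structure* of the confidential inputs:

- **Usual care:** one deterministic frozen distribution — the baseline
  allocation with a small placebo effect (2% of the cohort becomes
  seizure-free; 10% of high-frequency mass moves down a band).
- **CBD, cycles 1–9:** per cycle, a Dirichlet draw (concentration 200,
  emulating trial sampling noise) around the placebo distribution, on top of
  which the treatment effect moves `effect_size` (default 0.20) of the
  seizure-state mass into seizure-free and 25% of the remaining
  high-frequency mass down a band. The construction makes the expected arm
  difference in seizure-free occupancy equal `effect_size` exactly, and a
  projection step guarantees that the seizure-free-plus-low-frequency mass
  strictly exceeds usual care's at every cycle whenever `effect_size > 0`.
  Occupancy for cycles 2–9 is conditioned on remaining on treatment (the
  source material does not state its conditioning; this is the package's
  documented choice, not a fidelity claim).
- **Life table:** deterministic Gompertz-Makeham, annual hazard
  `μ(a) = A + B·cᵃ` with defaults A = 5·10⁻⁴, B = 3·10⁻⁵, c = 1.09 —
  a reasonable approximation to Dutch adult mortality that is reproducible
  without downloading national tables. Default excess rates (SUDEP
  0.0093/yr, non-SUDEP 0.0070/yr) are plausible DS-literature magnitudes,
  FICTIONAL-flagged.
- **Economic inputs:** published means and SEs where printed (utilities,
  care hours, age-band weights and proportions, ASM usage shares, care unit
  rates); everything else (unit costs, adverse-event rates and costs, CBD
  price per mg, daily ASM costs, discontinuation rates, responder fraction,
  caregiver decrement, alternative thresholds, literature resource use) is a
  FICTIONAL placeholder. `ModelConfig.fictional_parameters()` enumerates
  them, runs can refuse to proceed with them (`allow_fictional=False`), and
  every manifest lists them.

What passing tests therefore show: the engine, accrual, incremental and
sensitivity machinery are internally correct (mass conservation, oracle
equivalence against an independent individual-level simulator, closed-form
annuity limits, degeneracy and recovery properties) under study-shaped
inputs. What they do not show: agreement with the published euro/QALY totals,
which depend on confidential occupancy data and supplement-only unit costs.

## Numerical choices

- Distributions are validated to sum to 1 within 1e-9; traces conserve mass
  to the same tolerance without renormalization.
- Beta/gamma method-of-moments fits guard degenerate means (0 or 1 → point
  mass) and reject variances incompatible with the support before drawing.
- Problem sizes used by the shipped checks: 10⁴-patient oracle simulations,
  500-draw stochastic and 10 000-draw degenerate probabilistic analyses,
  1000-replicate generator-recovery runs — sizes at which binomial error
  bounds are tight enough to be informative while a full run of the suite
  stays comfortably interactive.
- Seeding: all randomness flows from `numpy.random.default_rng` seeded
  explicitly; identical (config, seed) pairs give byte-identical outputs.

## Known limitations

- One shared age clock per arm; background mortality is not conditioned on
  the evolving survivor age mix.
- The generator's placebo and treatment-effect magnitudes are stylized;
  scenario ICER shifts have qualitative, not quantitative, meaning.
- Institutionalization is costed per cycle alongside care hours, which may
  double-count informal care for institutionalized patients; the published
  costing detail needed to resolve this is not public.
- No value-of-information analysis and no multi-comparator frontier (only
  two strategies exist).
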