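"""Discounted QALY and cost accrual from cohort traces.

Payoffs accrue on full-cycle occupancy for cycles 1..N (row 0 of a trace is
the entry snapshot and accrues nothing); each cycle k is discounted by
``(1 + r)^(-k/4)``.  Cost categories:

* ``drug``           — CBD acquisition (weight-based dosing, drug-paying mass)
* ``asm``            — background antiseizure medications, both arms
* ``family_care``    — informal care at the replacement cost rate (societal only)
* ``professional_care`` — formal care hours
* ``hcru``           — emergency-department visits, nurse visits,
  hospitalizations (general-ward/ICU mix), institutionalization
* ``ae``             — adverse-event management, cycles 1-9 only
* ``travel``         — patient travel per visit (societal only)

The healthcare perspective zeroes ``family_care`` and ``travel``.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .config import FREQ_GROUPS, STATE_FREQ_GROUP, ModelConfig
from .model_types import (
    AgeBand,
    ConfigurationError,
    HealthState,
    ModelSettings,
    N_ALIVE,
)
from .cohort_engine import CohortTrace

COST_CATEGORIES = (
    "drug", "asm", "family_care", "professional_care", "hcru", "ae", "travel",
)
EVENT_KINDS = (
    "ed_visits", "nurse_visits", "hospitalizations", "institutionalizations", "hospital_days",
)


def discount_factor(cycle: int | np.ndarray, annual_rate: float) -> float | np.ndarray:
    """Discount multiplier ``(1 + r)^(-cycle/4)``; 1 at cycle 0."""
    return (1.0 + annual_rate) ** (-np.asarray(cycle, dtype=float) / 4.0)


def cycle_drug_cost(
    weight_kg: float,
    dose_mg_per_kg_day: float,
    price_per_mg: float,
    cycle_length_days: float,
) -> float:
    """Per-cycle CBD acquisition cost: weight x dose x days x unit price."""
    return weight_kg * dose_mg_per_kg_day * cycle_length_days * price_per_mg


def mean_weight_curve(age_bands: list[AgeBand], n_cycles: int) -> np.ndarray:
    """Cohort mean dosing weight per cycle.

    Each age band ages from its midpoint at a quarter year per cycle; a
    band's members take the mean weight of whichever band their current age
    falls into, so children grow into heavier bands and finally the adult
    band.  Returns an array of length ``n_cycles + 1``.
    """
    edges = np.array([b.lower_age for b in age_bands[1:]])
    weights = np.array([b.mean_weight_kg.mean for b in age_bands])
    props = np.array([b.proportion.mean for b in age_bands])
    props = props / props.sum()
    curve = np.zeros(n_cycles + 1)
    for t in range(n_cycles + 1):
        ages = np.array([b.midpoint + 0.25 * t for b in age_bands])
        idx = np.searchsorted(edges, ages, side="right")
        curve[t] = float(props @ weights[idx])
    return curve


def child_fraction_curve(age_bands: list[AgeBand], n_cycles: int) -> np.ndarray:
    """Fraction of the cohort younger than 18 per cycle (band-midpoint clock);
    drives the pediatric vs adult care-hours split."""
    props = np.array([b.proportion.mean for b in age_bands])
    props = props / props.sum()
    curve = np.zeros(n_cycles + 1)
    for t in range(n_cycles + 1):
        ages = np.array([b.midpoint + 0.25 * t for b in age_bands])
        curve[t] = float(props[ages < 18.0].sum())
    return curve


def _cycle_weights(trace: CohortTrace, settings: ModelSettings) -> np.ndarray:
    """Accrual weight per row: 0 for the entry snapshot, 1 per cycle (or the
    trapezoid weights under the half-cycle correction)."""
    n = trace.n_cycles
    w = np.ones(n + 1)
    w[0] = 0.0
    if settings.half_cycle_correction:
        w[0] = 0.5
        w[n] = 0.5
    return w


def accrue_qalys(
    trace: CohortTrace,
    config: ModelConfig,
    sae_prob: float = 0.0,
) -> float:
    """Discounted QALYs for one arm.

    Per cycle: occupancy . utilities x 0.25 years, minus the serious-adverse-
    event disutility (``sae_prob x |sae_disutility| x multiplier`` on the
    alive mass for the configured number of early cycles) and, in the
    caregiver scenario, the per-caregiver decrement on the alive mass.
    Dead contributes zero; negative state utilities accrue negatively.
    """
    u_cfg = config.utilities
    utilities = np.array(
        [u_cfg.state_utilities[s.name].mean for s in HealthState if s is not HealthState.DEAD]
    )
    settings = config.settings
    n = trace.n_cycles
    cycles = np.arange(n + 1)
    df = discount_factor(cycles, settings.qaly_discount_annual)
    w = _cycle_weights(trace, settings)
    occ = trace.occupancy[:, :N_ALIVE]
    per_cycle = occ @ utilities * 0.25

    alive = trace.alive
    disutility = abs(u_cfg.sae_disutility) * u_cfg.ae_disutility_multiplier
    if sae_prob > 0 and u_cfg.ae_disutility_cycles > 0:
        mask = (cycles >= 1) & (cycles <= min(u_cfg.ae_disutility_cycles, settings.ae_last_cycle))
        per_cycle = per_cycle - mask * sae_prob * disutility * 0.25 * alive
    if u_cfg.n_caregivers > 0:
        per_cycle = per_cycle - u_cfg.n_caregivers * u_cfg.caregiver_disutility.mean * 0.25 * alive

    return float(np.sum(per_cycle * df * w))


def _group_vector(per_group: dict[str, float]) -> np.ndarray:
    """Expand a frequency-group mapping to a length-5 alive-state vector."""
    return np.array(
        [per_group[STATE_FREQ_GROUP[s]] for s in HealthState if s is not HealthState.DEAD]
    )


def accrue_costs(
    trace: CohortTrace,
    config: ModelConfig,
    arm: str | None = None,
) -> dict[str, float]:
    """Discounted costs for one arm, itemized by category plus ``total``.

    Costs are linear in every unit cost, which the one-way sensitivity stage
    relies on.  The price-year multiplier scales all categories.
    """
    arm = arm or trace.arm
    settings = config.settings
    costs = config.costs
    n = trace.n_cycles
    cycles = np.arange(n + 1)
    df = discount_factor(cycles, settings.cost_discount_annual)
    w = _cycle_weights(trace, settings)
    occ = trace.occupancy[:, :N_ALIVE]
    alive = trace.alive
    weeks_per_cycle = settings.cycle_length_days / 7.0
    societal = config.perspective == "SOCIETAL"

    out: dict[str, float] = {}

    # drug acquisition — weight-based dosing over the drug-paying mass
    wt = mean_weight_curve(config.age_bands, n)
    per_mg = costs.cbd_price_per_mg.mean
    drug = trace.drug_frac * cycle_drug_cost(
        1.0, settings.cbd_dose_mg_per_kg_day, per_mg, settings.cycle_length_days
    ) * wt
    out["drug"] = float(np.sum(drug * df * w))

    # background antiseizure medications, both arms, alive mass
    asm_daily = sum(p.mean * daily for p, daily in costs.asm_usage.values())
    out["asm"] = float(np.sum(alive * asm_daily * settings.cycle_length_days * df * w))

    # care hours (weekly, by frequency group and pediatric/adult mix)
    child = child_fraction_curve(config.age_bands, n)
    fam_child = _group_vector({g: config.care_hours[g].family_child.mean for g in FREQ_GROUPS})
    fam_adult = _group_vector({g: config.care_hours[g].family_adult.mean for g in FREQ_GROUPS})
    pro_child = _group_vector({g: config.care_hours[g].professional_child.mean for g in FREQ_GROUPS})
    pro_adult = _group_vector({g: config.care_hours[g].professional_adult.mean for g in FREQ_GROUPS})
    fam_hours = child * (occ @ fam_child) + (1 - child) * (occ @ fam_adult)
    pro_hours = child * (occ @ pro_child) + (1 - child) * (occ @ pro_adult)
    fam_cost = fam_hours * weeks_per_cycle * costs.family_care_rate_per_hour
    pro_cost = pro_hours * weeks_per_cycle * costs.professional_care_rate_per_hour
    out["family_care"] = float(np.sum(fam_cost * df * w)) if societal else 0.0
    out["professional_care"] = float(np.sum(pro_cost * df * w))

    # healthcare resource use
    ed_p = _group_vector({g: config.hcru[g].ed_visit.mean for g in FREQ_GROUPS})
    nurse_p = _group_vector({g: config.hcru[g].nurse_visit.mean for g in FREQ_GROUPS})
    hosp_p = _group_vector({g: config.hcru[g].hospitalization.mean for g in FREQ_GROUPS})
    inst_p = _group_vector({g: config.hcru[g].institutionalized.mean for g in FREQ_GROUPS})
    days = _group_vector(
        {g: config.hcru[g].hospital_days_per_admission.mean for g in FREQ_GROUPS}
    )
    day_cost = (
        costs.icu_share * costs.icu_day_cost.mean
        + (1.0 - costs.icu_share) * costs.ward_day_cost.mean
    )
    hcru_per_state = (
        ed_p * costs.ed_visit_cost.mean
        + nurse_p * costs.nurse_visit_cost.mean
        + hosp_p * days * day_cost
        + inst_p * costs.institution_cycle_cost.mean
    )
    out["hcru"] = float(np.sum((occ @ hcru_per_state) * df * w))

    # adverse events, cycles 1..ae_last_cycle, arm-specific rates
    if arm == "CBD":
        ae_p, sae_p = costs.ae_prob_cbd.mean, costs.sae_prob_cbd.mean
    else:
        ae_p, sae_p = costs.ae_prob_usual_care.mean, costs.sae_prob_usual_care.mean
    ae_mask = (cycles >= 1) & (cycles <= settings.ae_last_cycle)
    ae_per_cycle = alive * (ae_p * costs.ae_cost.mean + sae_p * costs.sae_cost.mean)
    out["ae"] = float(
        np.sum(ae_per_cycle * ae_mask * df * w) * costs.ae_cost_multiplier
    )

    # travel per visit
    visits = occ @ (ed_p + nurse_p + hosp_p)
    travel = visits * costs.travel_cost_per_visit.mean
    out["travel"] = float(np.sum(travel * df * w)) if societal else 0.0

    for k in COST_CATEGORIES:
        out[k] *= costs.price_year_multiplier
    out["total"] = sum(out[k] for k in COST_CATEGORIES)
    return out


def count_events(trace: CohortTrace, config: ModelConfig) -> dict[str, float]:
    """Lifetime expected event counts per patient (undiscounted).

    Expected counts are the per-state per-cycle probabilities weighted by
    state occupancy, summed over the horizon; hospital days additionally
    weight admissions by the mean stay.
    """
    occ = trace.occupancy[1:, :N_ALIVE]
    ed_p = _group_vector({g: config.hcru[g].ed_visit.mean for g in FREQ_GROUPS})
    nurse_p = _group_vector({g: config.hcru[g].nurse_visit.mean for g in FREQ_GROUPS})
    hosp_p = _group_vector({g: config.hcru[g].hospitalization.mean for g in FREQ_GROUPS})
    inst_p = _group_vector({g: config.hcru[g].institutionalized.mean for g in FREQ_GROUPS})
    days = _group_vector(
        {g: config.hcru[g].hospital_days_per_admission.mean for g in FREQ_GROUPS}
    )
    return {
        "ed_visits": float((occ @ ed_p).sum()),
        "nurse_visits": float((occ @ nurse_p).sum()),
        "hospitalizations": float((occ @ hosp_p).sum()),
        "institutionalizations": float((occ @ inst_p).sum()),
        "hospital_days": float((occ @ (hosp_p * days)).sum()),
    }
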