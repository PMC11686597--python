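"""Markov cohort engine.

Each 3-month cycle, the surviving alive mass is redistributed across the
alive states according to the arm's occupancy profile (the stand-in for the
trial-derived transition data), mortality is applied per state, and — in the
CBD arm only — a fraction of on-treatment patients discontinues.  Discontinued
patients adopt the usual-care occupancy behaviour from the next cycle (or,
optionally, retain the distribution they held at discontinuation); with a
lag configured they keep paying for the drug for ``lag_cycles`` further
cycles at usual-care effectiveness.

Ordering within a cycle: redistribute -> record occupancy after deaths ->
discontinue (effective from the next cycle).  There is no half-cycle
correction in the base case; payoffs accrue on full-cycle occupancy.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .config import DiscontinuationConfig, ModelConfig
from .model_types import (
    BaselineAllocation,
    ConfigurationError,
    HealthState,
    ModelSettings,
    N_ALIVE,
    N_STATES,
    baseline_vector,
)
from .synthetic_inputs import Arm, ExcessMortality, LifeTable, OccupancyProfile

#: stopping-rule checkpoints: months since treatment start -> cycle index
STOPPING_CYCLE_FOR_MONTH = {6: 2, 12: 4, 24: 8}
_MONTH_FOR_CYCLE = {c: m for m, c in STOPPING_CYCLE_FOR_MONTH.items()}


def annual_prob_to_cycle(p_annual: float) -> float:
    """Convert an annual probability to a 3-month-cycle probability,
    ``1 - (1 - p)**(1/4)``, assuming a constant hazard within the year."""
    if not 0.0 <= p_annual <= 1.0:
        raise ConfigurationError(f"annual probability {p_annual} outside [0, 1]")
    return 1.0 - (1.0 - p_annual) ** 0.25


def cycle_death_prob(
    age: float,
    state: HealthState,
    life_table: LifeTable,
    excess: ExcessMortality,
) -> float:
    """Per-cycle death probability for an alive state at a given age.

    The background annual probability q(age) is converted to a hazard,
    the SUDEP and non-SUDEP excess hazards are added on the rate scale
    (scaled by the seizure-free risk ratio for the seizure-free state),
    and the combined hazard is converted back to a 3-month probability.
    """
    if state is HealthState.DEAD:
        raise ConfigurationError("death probability undefined for the dead state")
    q = life_table.annual_q(age)
    if q >= 1.0:
        return 1.0
    background_hazard = -np.log(1.0 - q)
    rr = excess.seizure_free_rr if state is HealthState.SEIZURE_FREE else 1.0
    excess_hazard = rr * (excess.sudep_annual_rate + excess.non_sudep_annual_rate)
    return float(1.0 - np.exp(-(background_hazard + excess_hazard) / 4.0))


def _death_prob_vector(
    age: float, life_table: LifeTable, excess: ExcessMortality
) -> np.ndarray:
    """Vectorized per-cycle death probabilities over the five alive states."""
    q = life_table.annual_q(age)
    if q >= 1.0:
        return np.ones(N_ALIVE)
    background = -np.log(1.0 - q)
    base_excess = excess.sudep_annual_rate + excess.non_sudep_annual_rate
    hazards = np.full(N_ALIVE, background + base_excess)
    hazards[HealthState.SEIZURE_FREE] = background + excess.seizure_free_rr * base_excess
    return 1.0 - np.exp(-hazards / 4.0)


def stopping_multiplier(
    cycle: int, responder_fraction: float, sched: DiscontinuationConfig
) -> float:
    """Retention multiplier from the stopping rule at this cycle.

    At cycles 2, 4 and 8 (months 6, 12, 24) the fraction of remaining
    patients without a >=30% seizure reduction who stop is
    ``stop_fraction * (1 - responder_fraction)``; other cycles return 1.
    """
    if not 0.0 <= responder_fraction <= 1.0:
        raise ConfigurationError("responder fraction must lie in [0, 1]")
    month = _MONTH_FOR_CYCLE.get(cycle)
    if month is None:
        return 1.0
    stop_fraction = sched.stopping_rule.get(month, 0.0)
    return 1.0 - stop_fraction * (1.0 - responder_fraction)


def apply_stopping_rule(
    on_cbd: float, cycle: int, responder_fraction: float, sched: DiscontinuationConfig
) -> float:
    """On-treatment fraction after the stopping rule at this cycle."""
    return on_cbd * stopping_multiplier(cycle, responder_fraction, sched)


@dataclasses.dataclass
class CohortTrace:
    """Cycle-by-cycle cohort fractions.

    ``occupancy[t]`` is the distribution over the six states during cycle t
    (row 0 is the baseline snapshot); ``on_cbd[t]`` the fraction of the cohort
    effectively on CBD; ``drug_frac[t]`` the fraction paying drug cost
    (``on_cbd`` plus any lagged discontinued mass); ``age_years[t]`` the mean
    cohort age.
    """

    arm: Arm
    occupancy: np.ndarray
    on_cbd: np.ndarray
    drug_frac: np.ndarray
    age_years: np.ndarray

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def alive(self) -> np.ndarray:
        return self.occupancy[:, :N_ALIVE].sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for t in range(self.occupancy.shape[0]):
            for s in HealthState:
                rows.append(
                    dict(
                        cycle=t,
                        state=s.name,
                        fraction=self.occupancy[t, s],
                        on_cbd=self.on_cbd[t],
                        drug_frac=self.drug_frac[t],
                        age_years=self.age_years[t],
                    )
                )
        return pd.DataFrame(rows)


def run_trace(
    arm: Arm,
    profile: OccupancyProfile,
    sched: DiscontinuationConfig | None,
    alloc: BaselineAllocation,
    life_table: LifeTable,
    excess: ExcessMortality,
    settings: ModelSettings,
    comparator_profile: OccupancyProfile | None = None,
    discontinuation_behaviour: str = "revert",
    effect_maintained: bool = True,
) -> CohortTrace:
    """Run the cohort trace for one arm over the full horizon.

    ``comparator_profile`` (the usual-care profile) is required for the CBD
    arm in "revert" mode, where discontinued patients adopt usual-care
    occupancy.  Passing a non-empty schedule with the usual-care arm is a
    configuration error: patients do not discontinue from usual care.
    """
    n = settings.n_cycles
    occupancy = np.zeros((n + 1, N_STATES))
    occupancy[0] = baseline_vector(alloc)
    on_arr = np.zeros(n + 1)
    drug_arr = np.zeros(n + 1)
    age0 = alloc.mean_age_years.mean
    age_arr = age0 + 0.25 * np.arange(n + 1)

    if arm == "USUAL_CARE":
        if sched is not None and not sched.is_empty():
            raise ConfigurationError("discontinuation schedules apply to the CBD arm only")
        on = 0.0
        off = 1.0
        sched = DiscontinuationConfig(
            short_term_cycle1=dict(mean=0.0),
            mid_term_per_cycle=dict(mean=0.0),
            long_term_per_cycle=dict(mean=0.0),
            stopping_rule={6: 0.0, 12: 0.0, 24: 0.0},
        )
    elif arm == "CBD":
        if sched is None:
            raise ConfigurationError("the CBD arm requires a discontinuation schedule")
        if discontinuation_behaviour == "revert" and comparator_profile is None:
            raise ConfigurationError(
                "revert mode requires the usual-care comparator profile"
            )
        on = 1.0
        off = 0.0
    else:
        raise ConfigurationError(f"unknown arm {arm!r}")

    on_arr[0] = on
    drug_arr[0] = on
    dead = 0.0
    lag: list[list[float]] = []  # [mass, cycles_remaining]
    off_dist: np.ndarray | None = None  # retain mode: occupancy of discontinued mass
    responder = sched.responder_fraction.mean

    for t in range(1, n + 1):
        if arm == "CBD":
            d_on = profile.distribution(t)
            if not effect_maintained and t > settings.freeze_cycle_cbd:
                d_on = comparator_profile.distribution(t)
            if discontinuation_behaviour == "revert":
                d_off = comparator_profile.distribution(t)
            else:
                d_off = off_dist if off_dist is not None else profile.distribution(t)
        else:
            d_on = d_off = profile.distribution(t)

        lag_total = sum(m for m, _ in lag)
        occ_alive = on * d_on + (off + lag_total) * d_off

        p_death = _death_prob_vector(age_arr[t], life_table, excess)
        survive = 1.0 - p_death
        dead += float(occ_alive @ p_death)
        occ_alive = occ_alive * survive

        s_on = float(d_on @ survive)
        s_off = float(d_off @ survive)
        on *= s_on
        off *= s_off
        for entry in lag:
            entry[0] *= s_off

        occupancy[t, :N_ALIVE] = occ_alive
        occupancy[t, HealthState.DEAD] = dead
        on_arr[t] = on
        drug_arr[t] = on + sum(m for m, _ in lag)

        # --- discontinuation, effective from the next cycle -------------
        if arm == "CBD" and on > 0:
            if t == 1:
                rate = sched.short_term_cycle1.mean
            elif t <= settings.freeze_cycle_cbd:
                rate = sched.mid_term_per_cycle.mean
            else:
                rate = sched.long_term_per_cycle.mean
                if sched.long_term_seizure_states_only:
                    rate *= float(d_on[1:].sum())
            retain = (1.0 - rate) * stopping_multiplier(t, responder, sched)
            leaving = on * (1.0 - retain)
            if leaving > 0:
                on -= leaving
                if discontinuation_behaviour == "retain":
                    prev = off + sum(m for m, _ in lag)
                    base = off_dist if off_dist is not None else d_on
                    total = prev + leaving
                    off_dist = (prev * base + leaving * d_on) / total if total > 0 else d_on
                if sched.lag_cycles > 0 and t > 1:
                    lag.append([leaving, sched.lag_cycles])
                else:
                    off += leaving
        # age the lag queue
        matured = 0.0
        kept = []
        for mass, remaining in lag:
            remaining -= 1
            if remaining <= 0:
                matured += mass
            else:
                kept.append([mass, remaining])
        lag = kept
        off += matured

    return CohortTrace(
        arm=arm, occupancy=occupancy, on_cbd=on_arr, drug_frac=drug_arr, age_years=age_arr
    )


def run_arm(config: ModelConfig, arm: Arm, bundle) -> CohortTrace:
    """Convenience wrapper running one arm from a config and input bundle."""
    return run_trace(
        arm=arm,
        profile=bundle.cbd_profile if arm == "CBD" else bundle.usual_care_profile,
        sched=config.discontinuation if arm == "CBD" else None,
        alloc=config.baseline,
        life_table=bundle.life_table,
        excess=bundle.excess_mortality,
        settings=config.settings,
        comparator_profile=bundle.usual_care_profile if arm == "CBD" else None,
        discontinuation_behaviour=config.discontinuation_behaviour,
        effect_maintained=config.effect_maintained,
    )
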