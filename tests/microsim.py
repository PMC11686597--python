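"""Independent individual-level Monte-Carlo simulator used as an oracle for
the cohort engine.

Implements the same rules — per-cycle occupancy sampling, hazard-added
mortality, cycle-banded discontinuation with the months-6/12/24 stopping rule
— at the level of individual patients, so cohort-trace expectations can be
checked against sampled frequencies within binomial error.  Deliberately
shares no code with the engine's update loop.
"""

from __future__ import annotations

import numpy as np

from epicua.cohort_engine import STOPPING_CYCLE_FOR_MONTH
from epicua.config import ModelConfig
from epicua.model_types import N_ALIVE, baseline_vector
from epicua.synthetic_inputs import InputBundle


def microsimulate(
    config: ModelConfig,
    bundle: InputBundle,
    arm: str,
    n_patients: int,
    seed: int,
    checkpoints: tuple[int, ...] = (1, 9, 40, 360),
):
    """Simulate ``n_patients`` individually; return per-checkpoint state
    frequencies (over the six states), the on-treatment fraction per
    checkpoint, and total sampled event counts per patient.
    """
    rng = np.random.default_rng(seed)
    settings = config.settings
    n_cycles = settings.n_cycles
    sched = config.discontinuation
    cbd_profile = bundle.cbd_profile
    uc_profile = bundle.usual_care_profile
    lt = bundle.life_table
    ex = bundle.excess_mortality
    hcru = config.hcru
    from epicua.config import FREQ_GROUPS, STATE_FREQ_GROUP
    from epicua.model_types import HealthState

    def group_vec(field):
        return np.array([
            getattr(hcru[STATE_FREQ_GROUP[s]], field).mean
            for s in HealthState if s is not HealthState.DEAD
        ])

    ed_p, nurse_p, hosp_p, inst_p = (
        group_vec("ed_visit"), group_vec("nurse_visit"),
        group_vec("hospitalization"), group_vec("institutionalized"),
    )
    days = group_vec("hospital_days_per_admission")

    alive = np.ones(n_patients, dtype=bool)
    on = np.full(n_patients, arm == "CBD")
    # baseline states sampled from the allocation
    base = baseline_vector(config.baseline)
    states = rng.choice(6, size=n_patients, p=base / base.sum())
    age0 = config.baseline.mean_age_years.mean
    base_excess = ex.sudep_annual_rate + ex.non_sudep_annual_rate

    stop_cycles = {c: sched.stopping_rule.get(m, 0.0)
                   for m, c in STOPPING_CYCLE_FOR_MONTH.items()}
    responder = sched.responder_fraction.mean

    freqs: dict[int, np.ndarray] = {}
    on_frac: dict[int, float] = {}
    events = dict.fromkeys(
        ("ed_visits", "nurse_visits", "hospitalizations", "institutionalizations"), 0.0
    )
    events["hospital_days"] = 0.0

    for t in range(1, n_cycles + 1):
        # redistribute: alive patients draw a fresh state from their profile
        if alive.any():
            d_cbd = cbd_profile.distribution(t)
            d_uc = uc_profile.distribution(t)
            idx_on = np.flatnonzero(alive & on)
            idx_off = np.flatnonzero(alive & ~on)
            states[idx_on] = rng.choice(N_ALIVE, size=len(idx_on), p=d_cbd)
            states[idx_off] = rng.choice(N_ALIVE, size=len(idx_off), p=d_uc)
        # mortality: hazard addition, seizure-free risk ratio on the excess term
        age = age0 + 0.25 * t
        q = lt.annual_q(age)
        background = -np.log(1.0 - q) if q < 1 else np.inf
        excess = np.where(states == 0, ex.seizure_free_rr * base_excess, base_excess)
        p_die = 1.0 - np.exp(-(background + excess) / 4.0)
        dies = alive & (rng.random(n_patients) < p_die)
        alive &= ~dies
        states[dies] = 5
        on &= alive

        if t in checkpoints:
            freqs[t] = np.bincount(states, minlength=6) / n_patients
            on_frac[t] = on.mean()

        # events for patients alive this cycle
        live_states = states[alive]
        u = rng.random((live_states.size, 4))
        events["ed_visits"] += (u[:, 0] < ed_p[live_states]).sum()
        events["nurse_visits"] += (u[:, 1] < nurse_p[live_states]).sum()
        hosp = u[:, 2] < hosp_p[live_states]
        events["hospitalizations"] += hosp.sum()
        events["hospital_days"] += days[live_states][hosp].sum()
        events["institutionalizations"] += (u[:, 3] < inst_p[live_states]).sum()

        # discontinuation (CBD arm), effective next cycle
        if arm == "CBD" and on.any():
            if t == 1:
                rate = sched.short_term_cycle1.mean
            elif t <= settings.freeze_cycle_cbd:
                rate = sched.mid_term_per_cycle.mean
            else:
                rate = sched.long_term_per_cycle.mean
            leave_p = 1.0 - (1.0 - rate) * (
                1.0 - stop_cycles.get(t, 0.0) * (1.0 - responder)
            )
            quits = on & (rng.random(n_patients) < leave_p)
            on &= ~quits

    for k in events:
        events[k] /= n_patients
    return freqs, on_frac, events
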