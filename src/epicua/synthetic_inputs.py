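"""Synthetic stand-ins for the confidential trial-derived model inputs.

The published analysis sources per-cycle health-state occupancy from
patient-level trial data that are not public, and its background mortality
from national life tables.  This module generates statistically analogous
inputs so the whole pipeline is runnable and testable offline:

* per-cycle occupancy profiles for a CBD arm (cycle 1 trial effect, cycles
  2-9 open-label extension, frozen thereafter) and a usual-care arm (single
  frozen placebo-effect distribution from cycle 1);
* a Gompertz-Makeham life table approximating Dutch all-cause mortality;
* the economic parameter set (utilities, care hours, unit costs) with the
  published means and standard errors where they exist.

Nothing here is calibrated to reproduce the published euro totals; the
generator only reproduces the *structure* the downstream stages assume.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np
from pydantic import BaseModel, Field

from .config import ModelConfig, default_config
from .model_types import (
    ConfigurationError,
    HealthState,
    N_ALIVE,
    baseline_vector,
)

Arm = Literal["CBD", "USUAL_CARE"]


class GeneratorSpec(BaseModel):
    """Seeded specification for one synthetic occupancy draw."""

    seed: int = 0
    effect_size: float = 0.20
    noise_concentration: float = Field(default=200.0, gt=0)
    placebo_seizure_free: float = Field(default=0.02, ge=0, le=1)
    placebo_shift: float = Field(default=0.10, ge=0, le=1)
    cbd_shift: float = Field(default=0.25, ge=0, le=1)

    @classmethod
    def from_config(cls, config: ModelConfig, seed: int) -> "GeneratorSpec":
        g = config.generator
        return cls(
            seed=seed,
            effect_size=g.effect_size,
            noise_concentration=g.noise_concentration,
            placebo_seizure_free=g.placebo_seizure_free,
            placebo_shift=g.placebo_shift,
            cbd_shift=g.cbd_shift,
        )


@dataclasses.dataclass(frozen=True)
class OccupancyProfile:
    """Per-cycle distribution over the five alive states, conditional on being
    alive and (for the CBD arm) on treatment.

    The usual-care profile holds a single entry (cycle 1, frozen for life);
    the CBD profile holds cycles 1..freeze_cycle and is frozen at the last
    entry thereafter.
    """

    arm: Arm
    per_cycle: dict[int, np.ndarray]

    def __post_init__(self) -> None:
        for c, dist in self.per_cycle.items():
            if dist.shape != (N_ALIVE,):
                raise ConfigurationError(f"cycle {c}: distribution must have {N_ALIVE} entries")
            if not np.isclose(dist.sum(), 1.0, atol=1e-9):
                raise ConfigurationError(f"cycle {c}: distribution must sum to 1")

    @property
    def max_cycle(self) -> int:
        return max(self.per_cycle)

    def distribution(self, cycle: int) -> np.ndarray:
        """Conditional alive-state distribution in effect at ``cycle`` (>= 1)."""
        if cycle < 1:
            raise ConfigurationError("occupancy profiles start at cycle 1")
        return self.per_cycle[min(cycle, self.max_cycle)]

    def to_matrix(self) -> np.ndarray:
        cycles = sorted(self.per_cycle)
        return np.vstack([self.per_cycle[c] for c in cycles])


@dataclasses.dataclass(frozen=True)
class LifeTable:
    """Annual probability of death q(a) for integer ages ``age_min..age_max``."""

    age_min: int
    q: np.ndarray  # q[i] is the probability of dying between age_min+i and +i+1

    def annual_q(self, age: float) -> float:
        """q for the year of age containing ``age``; terminal q beyond the table."""
        idx = int(np.floor(age)) - self.age_min
        idx = min(max(idx, 0), len(self.q) - 1)
        return float(self.q[idx])

    @property
    def age_max(self) -> int:
        return self.age_min + len(self.q) - 1


@dataclasses.dataclass(frozen=True)
class ExcessMortality:
    """Condition-specific excess mortality on top of the life table."""

    sudep_annual_rate: float
    non_sudep_annual_rate: float
    seizure_free_rr: float = 1.0

    def __post_init__(self) -> None:
        if self.sudep_annual_rate < 0 or self.non_sudep_annual_rate < 0:
            raise ConfigurationError("excess mortality rates must be nonnegative")
        if not 0 < self.seizure_free_rr <= 1:
            raise ConfigurationError("seizure-free risk ratio must lie in (0, 1]")

    @classmethod
    def from_config(cls, config: ModelConfig) -> "ExcessMortality":
        m = config.mortality
        return cls(
            sudep_annual_rate=m.sudep_annual_rate.mean,
            non_sudep_annual_rate=m.non_sudep_annual_rate.mean,
            seizure_free_rr=m.seizure_free_rr,
        )


# ---------------------------------------------------------------------------
# Occupancy generation
# ---------------------------------------------------------------------------

def _placebo_distribution(config: ModelConfig, spec: GeneratorSpec) -> np.ndarray:
    """Frozen usual-care distribution: baseline plus a small placebo effect.

    A fraction ``placebo_seizure_free`` of the cohort becomes seizure-free
    (drawn proportionally from all seizure states) and ``placebo_shift`` of
    the remaining high-frequency mass moves down to the matching low-frequency
    sub-state.
    """
    base = baseline_vector(config.baseline)[:N_ALIVE].copy()
    seized = base[1:].sum()
    if seized > 0:
        take = spec.placebo_seizure_free
        base[1:] *= 1.0 - take / seized
        base[0] += take
    # shift high-frequency mass to the low-frequency state with the same SFD level
    for hi, lo in ((3, 1), (4, 2)):
        moved = spec.placebo_shift * base[hi]
        base[hi] -= moved
        base[lo] += moved
    return base / base.sum()


def _apply_treatment_effect(dist: np.ndarray, spec: GeneratorSpec) -> np.ndarray:
    """Move mass toward milder states: ``effect_size`` from the seizure states
    to seizure-free, then ``cbd_shift`` of remaining high-frequency mass down
    one frequency band."""
    out = dist.copy()
    seized = out[1:].sum()
    take = min(spec.effect_size, seized)
    if seized > 0:
        out[1:] *= 1.0 - take / seized
        out[0] += take
    for hi, lo in ((3, 1), (4, 2)):
        moved = spec.cbd_shift * out[hi]
        out[hi] -= moved
        out[lo] += moved
    return out / out.sum()


def _enforce_benefit(cbd: np.ndarray, uc: np.ndarray, effect_size: float) -> np.ndarray:
    """Projection guaranteeing the generator contract: when effect_size > 0 the
    CBD seizure-free + low-frequency mass strictly exceeds usual care's."""
    if effect_size <= 0:
        return cbd
    target = uc[0] + uc[1] + uc[2] + 0.5 * effect_size
    current = cbd[0] + cbd[1] + cbd[2]
    if current > target:
        return cbd
    deficit = target - current
    high = cbd[3] + cbd[4]
    moved = min(deficit, high * 0.95)
    out = cbd.copy()
    if high > 0:
        out[3] -= moved * cbd[3] / high
        out[4] -= moved * cbd[4] / high
        out[0] += moved
    return out / out.sum()


def generate_occupancy(
    spec: GeneratorSpec, arm: Arm, config: ModelConfig
) -> OccupancyProfile:
    """Generate a synthetic occupancy profile for one arm.

    Usual care: one deterministic frozen distribution (the cycle-1 placebo
    effect, maintained for life).  CBD: cycles 1..freeze_cycle, each a
    Dirichlet draw (concentration ``noise_concentration``) around the placebo
    distribution with the treatment effect applied on top.  The construction
    keeps the mean arm difference in seizure-free occupancy equal to
    ``effect_size`` and guarantees the milder-state mass advantage at every
    cycle whenever ``effect_size > 0``.
    """
    if spec.noise_concentration <= 0:
        raise ConfigurationError("noise concentration must be positive")
    uc_dist = _placebo_distribution(config, spec)
    if arm == "USUAL_CARE":
        return OccupancyProfile(arm=arm, per_cycle={1: uc_dist})
    if arm != "CBD":
        raise ConfigurationError(f"unknown arm {arm!r}")

    rng = np.random.default_rng(spec.seed)
    per_cycle: dict[int, np.ndarray] = {}
    for cycle in range(1, config.settings.freeze_cycle_cbd + 1):
        alpha = np.maximum(uc_dist * spec.noise_concentration, 1e-6)
        noisy = rng.dirichlet(alpha)
        treated = _apply_treatment_effect(noisy, spec)
        per_cycle[cycle] = _enforce_benefit(treated, uc_dist, spec.effect_size)
    return OccupancyProfile(arm="CBD", per_cycle=per_cycle)


# ---------------------------------------------------------------------------
# Life table
# ---------------------------------------------------------------------------

def generate_life_table(
    makeham_a: float = 5e-4,
    makeham_b: float = 3e-5,
    makeham_c: float = 1.09,
    age_min: int = 2,
    age_max: int = 100,
) -> LifeTable:
    """Deterministic Gompertz-Makeham life table.

    The annual hazard at age ``a`` is ``mu(a) = A + B * c**a`` (constant
    within each year of age), giving ``q(a) = 1 - exp(-mu(a))``; values are
    clamped at 1 should the hazard explode before ``age_max``.
    """
    if makeham_a < 0 or makeham_b < 0 or makeham_c <= 1:
        raise ConfigurationError("Gompertz-Makeham parameters must be positive (c > 1)")
    ages = np.arange(age_min, age_max + 1, dtype=float)
    hazard = makeham_a + makeham_b * makeham_c ** ages
    q = 1.0 - np.exp(-hazard)
    return LifeTable(age_min=age_min, q=np.clip(q, 0.0, 1.0))


def life_table_from_config(config: ModelConfig) -> LifeTable:
    m = config.mortality
    return generate_life_table(m.makeham_a, m.makeham_b, m.makeham_c)


def gompertz_makeham_survival(
    age: float,
    age_min: int = 2,
    makeham_a: float = 5e-4,
    makeham_b: float = 3e-5,
    makeham_c: float = 1.09,
) -> float:
    """Closed-form survivor function from ``age_min`` to ``age`` under the
    piecewise-constant annual hazard used by :func:`generate_life_table`."""
    k = int(age) - age_min
    if k <= 0:
        return 1.0
    cumulative = makeham_a * k + makeham_b * makeham_c**age_min * (
        (makeham_c**k - 1.0) / (makeham_c - 1.0)
    )
    return float(np.exp(-cumulative))


# ---------------------------------------------------------------------------
# Full bundle
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class InputBundle:
    """Everything the engine needs for one condition: both occupancy profiles,
    the life table and excess-mortality rates, plus the source config."""

    config: ModelConfig
    cbd_profile: OccupancyProfile
    usual_care_profile: OccupancyProfile
    life_table: LifeTable
    excess_mortality: ExcessMortality


def generate_inputs(config: ModelConfig, seed: int) -> InputBundle:
    """Generate the complete synthetic input bundle, deterministically in
    (config, seed)."""
    spec = GeneratorSpec.from_config(config, seed)
    return InputBundle(
        config=config,
        cbd_profile=generate_occupancy(spec, "CBD", config),
        usual_care_profile=generate_occupancy(spec, "USUAL_CARE", config),
        life_table=life_table_from_config(config),
        excess_mortality=ExcessMortality.from_config(config),
    )


def generate_economic_inputs(condition_name: str, seed: int = 0) -> ModelConfig:
    """The economic parameter set (utilities, care hours, costs with means,
    SEs and sensitivity-analysis distribution families) for a condition.

    Published values carry their published means/SEs; unit costs without a
    public source are FICTIONAL-flagged placeholders.  The set is
    deterministic — ``seed`` is accepted for interface symmetry with the
    other generators but sampling happens only downstream (in the
    probabilistic sensitivity analysis), never here.
    """
    del seed
    return default_config(condition_name)
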