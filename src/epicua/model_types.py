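"""Shared domain types for the seizure-frequency Markov cohort model.

The model tracks a cohort of patients with a severe epileptic encephalopathy
(Lennox-Gastaut syndrome, LGS, or Dravet syndrome, DS) through six mutually
exclusive health states defined by seizure frequency and, within each seizure
state, the number of seizure-free days (SFD) per month:

====================  =====================================================
state                 meaning
====================  =====================================================
SEIZURE_FREE          no qualifying seizures; no SFD sub-split
LOW_FREQ_LOW_SFD      at or below the seizure threshold, few SFD
LOW_FREQ_HIGH_SFD     at or below the seizure threshold, many SFD
HIGH_FREQ_LOW_SFD     above the seizure threshold, few SFD
HIGH_FREQ_HIGH_SFD    above the seizure threshold, many SFD
DEAD                  absorbing
====================  =====================================================

The LGS and DS models are structurally identical; only the thresholds that
define the frequency split (55 drop seizures vs 12 convulsive seizures per
month) and the SFD split (15 vs 18 days per month) differ.
"""

from __future__ import annotations

import enum
from typing import Literal

import numpy as np
from pydantic import BaseModel, Field, model_validator


class ConfigurationError(ValueError):
    """Raised when model configuration is internally inconsistent."""


class HealthState(enum.IntEnum):
    """The six compartments, in the canonical serialization order."""

    SEIZURE_FREE = 0
    LOW_FREQ_LOW_SFD = 1
    LOW_FREQ_HIGH_SFD = 2
    HIGH_FREQ_LOW_SFD = 3
    HIGH_FREQ_HIGH_SFD = 4
    DEAD = 5


N_STATES = 6
ALIVE_STATES = tuple(s for s in HealthState if s is not HealthState.DEAD)
N_ALIVE = len(ALIVE_STATES)
# indices of the four states with ongoing seizures (used by the
# seizure-states-only discontinuation scenario)
SEIZURE_STATE_INDICES = (1, 2, 3, 4)


class Param(BaseModel):
    """A scalar model input with its sampling uncertainty.

    ``dist`` names the probabilistic-sensitivity-analysis family; ``fixed``
    means the parameter is never redrawn.  ``fictional`` flags placeholder
    values that do not come from a published table and must be reviewed
    before any real-world use.
    """

    mean: float
    se: float = 0.0
    dist: Literal["fixed", "beta", "gamma", "normal", "truncnorm"] = "fixed"
    fictional: bool = False

    def bounds(self, se_fallback_fraction: float = 0.20) -> tuple[float, float]:
        """Deterministic-sensitivity bounds: mean +/- 1.96 SE, or +/-20% of the
        mean when no standard error is available."""
        if self.se > 0:
            lo, hi = self.mean - 1.96 * self.se, self.mean + 1.96 * self.se
        else:
            delta = abs(self.mean) * se_fallback_fraction
            lo, hi = self.mean - delta, self.mean + delta
        return (min(lo, hi), max(lo, hi))


class Condition(BaseModel):
    """An indication with its seizure-frequency and seizure-free-day cutoffs."""

    name: Literal["LGS", "DS"]
    seizure_threshold: int = Field(gt=0)
    seizure_free_day_threshold: int = Field(gt=0)

    @property
    def is_reference(self) -> bool:
        """Whether the thresholds are the published ones (non-reference
        values are legal: the alternative-thresholds scenario uses them)."""
        return (self.seizure_threshold, self.seizure_free_day_threshold) == {
            "LGS": (55, 15),
            "DS": (12, 18),
        }[self.name]


def lgs() -> Condition:
    """LGS: frequency split at 55 drop seizures/month, SFD split at 15 days."""
    return Condition(name="LGS", seizure_threshold=55, seizure_free_day_threshold=15)


def ds() -> Condition:
    """DS: frequency split at 12 convulsive seizures/month, SFD split at 18 days."""
    return Condition(name="DS", seizure_threshold=12, seizure_free_day_threshold=18)


def condition_from_name(name: str) -> Condition:
    if name == "LGS":
        return lgs()
    if name == "DS":
        return ds()
    raise ConfigurationError(f"unknown condition {name!r}; expected 'LGS' or 'DS'")


class ModelSettings(BaseModel):
    """Global engine settings (cycle structure, discounting, dosing)."""

    cycle_length_days: float = 365.25 / 4
    horizon_years: float = 90.0
    cost_discount_annual: float = Field(default=0.040, ge=0, lt=1)
    qaly_discount_annual: float = Field(default=0.015, ge=0, lt=1)
    wtp_per_qaly: float = 80_000.0
    cohort_size: int = 10_000
    cbd_dose_mg_per_kg_day: float = Field(default=12.0, ge=5.0, le=20.0)
    freeze_cycle_cbd: int = 9
    freeze_cycle_usual_care: int = 1
    ae_last_cycle: int = 9
    half_cycle_correction: bool = False

    @property
    def n_cycles(self) -> int:
        """Number of 3-month cycles over the horizon (360 in the base case)."""
        return int(round(self.horizon_years * 4))


class AgeBand(BaseModel):
    """Age band with its baseline share of the cohort and mean body weight.

    Weight drives weight-based dosing; the band clock (midpoint age, advanced
    a quarter year per cycle) moves children into heavier bands over time.
    """

    lower_age: float
    upper_age: float
    proportion: Param
    mean_weight_kg: Param

    @model_validator(mode="after")
    def _check(self) -> "AgeBand":
        if self.upper_age <= self.lower_age:
            raise ConfigurationError("age band upper bound must exceed lower bound")
        if self.mean_weight_kg.mean <= 0:
            raise ConfigurationError("mean weight must be positive")
        return self

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lower_age + self.upper_age)


def validate_age_bands(bands: list[AgeBand], tol: float = 0.005) -> None:
    total = sum(b.proportion.mean for b in bands)
    if abs(total - 1.0) > tol:
        raise ConfigurationError(
            f"age-band proportions sum to {total:.4f}, expected 1 within {tol}"
        )


class BaselineAllocation(BaseModel):
    """Where the cohort starts.

    ``frequency_split`` is the fraction in the high-frequency state;
    ``sfd_split_within_frequency`` gives, per frequency state, the fraction in
    the low-SFD sub-state (few seizure-free days).  All entrants have active
    seizures, so no baseline mass is placed in SEIZURE_FREE or DEAD.
    """

    mean_age_years: Param
    frequency_split: Param
    sfd_split_within_frequency: dict[Literal["low", "high"], Param]

    @model_validator(mode="after")
    def _check(self) -> "BaselineAllocation":
        for p in (
            self.frequency_split,
            self.sfd_split_within_frequency["low"],
            self.sfd_split_within_frequency["high"],
        ):
            if not 0.0 <= p.mean <= 1.0:
                raise ConfigurationError("baseline split fractions must lie in [0, 1]")
        return self


def build_state_space(condition: Condition) -> list[HealthState]:
    """Return the six states in the canonical order (DEAD last).

    The state space is identical for LGS and DS; condition thresholds only
    change how states are labelled, via :func:`state_descriptions`.
    """
    if condition.name not in ("LGS", "DS"):  # pragma: no cover - pydantic guards
        raise ConfigurationError(f"unknown condition {condition.name!r}")
    return list(HealthState)


def state_descriptions(condition: Condition) -> dict[HealthState, str]:
    """Human-readable state labels with the condition's thresholds filled in."""
    s, d = condition.seizure_threshold, condition.seizure_free_day_threshold
    kind = "drop" if condition.name == "LGS" else "convulsive"
    return {
        HealthState.SEIZURE_FREE: f"seizure-free (no {kind} seizures)",
        HealthState.LOW_FREQ_LOW_SFD: f"≤{s} {kind} seizures/month, ≤{d} seizure-free days",
        HealthState.LOW_FREQ_HIGH_SFD: f"≤{s} {kind} seizures/month, >{d} seizure-free days",
        HealthState.HIGH_FREQ_LOW_SFD: f">{s} {kind} seizures/month, ≤{d} seizure-free days",
        HealthState.HIGH_FREQ_HIGH_SFD: f">{s} {kind} seizures/month, >{d} seizure-free days",
        HealthState.DEAD: "dead",
    }


def baseline_vector(alloc: BaselineAllocation) -> np.ndarray:
    """Baseline probability vector over the six states.

    Sub-state splits are conditional on the frequency state, so each seizure
    compartment receives ``freq_share * sfd_share``.  Sums to 1 exactly; zero
    mass in SEIZURE_FREE and DEAD.
    """
    high = alloc.frequency_split.mean
    low = 1.0 - high
    low_sfd_low = alloc.sfd_split_within_frequency["low"].mean
    low_sfd_high = alloc.sfd_split_within_frequency["high"].mean
    vec = np.zeros(N_STATES)
    vec[HealthState.LOW_FREQ_LOW_SFD] = low * low_sfd_low
    vec[HealthState.LOW_FREQ_HIGH_SFD] = low * (1.0 - low_sfd_low)
    vec[HealthState.HIGH_FREQ_LOW_SFD] = high * low_sfd_high
    vec[HealthState.HIGH_FREQ_HIGH_SFD] = high * (1.0 - low_sfd_high)
    return vec
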