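"""Model configuration: the full input tree, per-condition defaults, and
loading/validation from JSON or YAML.

Published inputs (demographics, baseline allocation, care hours, utilities,
antiseizure-medication usage shares) carry their published means and standard
errors.  Inputs that are not publicly printed anywhere — unit costs of
healthcare resource use, adverse-event costs, travel cost, daily ASM costs,
the cannabidiol price per mg, the caregiver utility decrement — ship as
plausible placeholders flagged ``fictional=True`` and are logged whenever a
report uses them.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, model_validator

from .model_types import (
    AgeBand,
    BaselineAllocation,
    Condition,
    ConfigurationError,
    HealthState,
    Param,
    ModelSettings,
    condition_from_name,
    validate_age_bands,
)

FREQ_GROUPS = ("seizure_free", "low_freq", "high_freq")

#: mapping from alive-state index to its frequency group for costing tables
STATE_FREQ_GROUP = {
    HealthState.SEIZURE_FREE: "seizure_free",
    HealthState.LOW_FREQ_LOW_SFD: "low_freq",
    HealthState.LOW_FREQ_HIGH_SFD: "low_freq",
    HealthState.HIGH_FREQ_LOW_SFD: "high_freq",
    HealthState.HIGH_FREQ_HIGH_SFD: "high_freq",
}


class GeneratorConfig(BaseModel):
    """Synthetic occupancy-profile generator settings.

    ``effect_size`` is the target CBD-minus-usual-care difference in
    seizure-free occupancy (conditional on alive, on treatment).
    ``placebo_seizure_free`` and ``placebo_shift`` define the frozen
    usual-care (placebo) distribution relative to baseline.
    """

    effect_size: float = 0.20
    placebo_seizure_free: float = 0.02
    placebo_shift: float = 0.10
    cbd_shift: float = 0.25
    noise_concentration: float = Field(default=200.0, gt=0)


class MortalityConfig(BaseModel):
    """Background life table (Gompertz-Makeham) plus epilepsy excess mortality.

    SUDEP and non-SUDEP excess rates are annual per-person hazards added to
    the background hazard; the same rates are used for LGS and DS.  In the
    base case mortality is equal across alive states; the risk-ratio scenario
    multiplies the excess component by ``seizure_free_rr`` for seizure-free
    patients.
    """

    makeham_a: float = Field(default=5e-4, ge=0)
    makeham_b: float = Field(default=3e-5, ge=0)
    makeham_c: float = Field(default=1.09, gt=1)
    sudep_annual_rate: Param = Param(mean=0.0093, se=0.0, dist="gamma", fictional=True)
    non_sudep_annual_rate: Param = Param(mean=0.0070, se=0.0, dist="gamma", fictional=True)
    seizure_free_rr: float = Field(default=1.0, gt=0, le=1.0)


class DiscontinuationConfig(BaseModel):
    """CBD treatment-withdrawal schedule (never applied to usual care).

    Cycle 1 uses the adverse-event-driven trial rate; cycles 2-9 the
    all-cause open-label-extension rate; cycles 10+ a constant long-term
    rate (4.17% base case).  The stopping rule removes, at months 6/12/24
    (cycles 2/4/8), a one-off fraction of patients without a >=30% seizure
    reduction.  ``lag_cycles`` keeps drug cost (without benefit) for that
    many cycles after loss of effect (0 base case, 2 in the 6-month-lag
    scenario).
    """

    short_term_cycle1: Param = Param(mean=0.09, se=0.0, dist="beta", fictional=True)
    mid_term_per_cycle: Param = Param(mean=0.035, se=0.0, dist="beta", fictional=True)
    long_term_per_cycle: Param = Param(mean=0.0417, se=0.0, dist="beta")
    stopping_rule: dict[int, float] = Field(
        default_factory=lambda: {6: 0.5, 12: 0.3, 24: 0.2}
    )
    responder_fraction: Param = Param(mean=0.55, se=0.0, dist="beta", fictional=True)
    lag_cycles: int = Field(default=0, ge=0)
    long_term_seizure_states_only: bool = False

    @model_validator(mode="after")
    def _check(self) -> "DiscontinuationConfig":
        for p in (self.short_term_cycle1, self.mid_term_per_cycle, self.long_term_per_cycle):
            if not 0.0 <= p.mean <= 1.0:
                raise ConfigurationError("discontinuation fractions must lie in [0, 1]")
        if set(self.stopping_rule) - {6, 12, 24}:
            raise ConfigurationError("stopping-rule months must be among {6, 12, 24}")
        return self

    def is_empty(self) -> bool:
        return (
            self.short_term_cycle1.mean == 0
            and self.mid_term_per_cycle.mean == 0
            and self.long_term_per_cycle.mean == 0
            and all(v == 0 for v in self.stopping_rule.values())
        )


class UtilityConfig(BaseModel):
    """Health-state utilities (time trade-off vignette study) and disutilities."""

    state_utilities: dict[str, Param]
    sae_disutility: float = Field(default=-0.12, le=0)
    ae_disutility_multiplier: float = 1.0
    ae_disutility_cycles: int = Field(default=1, ge=0, le=9)
    caregiver_disutility: Param = Param(mean=0.15, se=0.0, dist="beta", fictional=True)
    n_caregivers: int = Field(default=0, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "UtilityConfig":
        expected = {s.name for s in HealthState if s is not HealthState.DEAD}
        if set(self.state_utilities) != expected:
            raise ConfigurationError(
                f"state_utilities keys must be exactly {sorted(expected)}"
            )
        for p in self.state_utilities.values():
            if not -1.0 <= p.mean <= 1.0:
                raise ConfigurationError("utilities must lie in [-1, 1]")
        return self


class CareHoursGroup(BaseModel):
    """Weekly informal (family) and professional care hours for one frequency
    group, split by pediatric (2-17 y) vs adult (18-55 y) patients."""

    family_child: Param
    family_adult: Param
    professional_child: Param
    professional_adult: Param


class HcruGroup(BaseModel):
    """Per-cycle healthcare-resource-use probabilities for one frequency group."""

    ed_visit: Param
    nurse_visit: Param
    hospitalization: Param
    institutionalized: Param
    hospital_days_per_admission: Param


class CostConfig(BaseModel):
    """Unit costs and event probabilities (2019/2020 euros unless scaled)."""

    cbd_price_per_mg: Param = Param(mean=0.11, se=0.0, dist="gamma", fictional=True)
    family_care_rate_per_hour: float = 14.95   # replacement cost
    professional_care_rate_per_hour: float = 53.40
    ed_visit_cost: Param = Param(mean=280.0, se=0.0, dist="gamma", fictional=True)
    nurse_visit_cost: Param = Param(mean=120.0, se=0.0, dist="gamma", fictional=True)
    ward_day_cost: Param = Param(mean=650.0, se=0.0, dist="gamma", fictional=True)
    icu_day_cost: Param = Param(mean=2500.0, se=0.0, dist="gamma", fictional=True)
    icu_share: float = Field(default=0.10, ge=0, le=1)
    institution_cycle_cost: Param = Param(mean=6000.0, se=0.0, dist="gamma", fictional=True)
    travel_cost_per_visit: Param = Param(mean=25.0, se=0.0, dist="gamma", fictional=True)
    ae_prob_cbd: Param = Param(mean=0.18, se=0.0, dist="beta", fictional=True)
    ae_prob_usual_care: Param = Param(mean=0.08, se=0.0, dist="beta", fictional=True)
    ae_cost: Param = Param(mean=150.0, se=0.0, dist="gamma", fictional=True)
    sae_prob_cbd: Param = Param(mean=0.030, se=0.0, dist="beta", fictional=True)
    sae_prob_usual_care: Param = Param(mean=0.012, se=0.0, dist="beta", fictional=True)
    sae_cost: Param = Param(mean=2500.0, se=0.0, dist="gamma", fictional=True)
    asm_usage: dict[str, tuple[Param, float]] = Field(default_factory=dict)
    price_year_multiplier: float = 1.0
    ae_cost_multiplier: float = 1.0


class ModelConfig(BaseModel):
    """The complete, self-contained input set for one condition."""

    condition: Condition
    settings: ModelSettings = ModelSettings()
    perspective: Literal["SOCIETAL", "HEALTHCARE"] = "SOCIETAL"
    age_bands: list[AgeBand]
    baseline: BaselineAllocation
    generator: GeneratorConfig = GeneratorConfig()
    mortality: MortalityConfig = MortalityConfig()
    discontinuation: DiscontinuationConfig = DiscontinuationConfig()
    utilities: UtilityConfig
    care_hours: dict[str, CareHoursGroup]
    hcru: dict[str, HcruGroup]
    costs: CostConfig = CostConfig()
    # Discontinued patients revert to usual-care occupancy ("revert") or keep
    # their distribution at discontinuation ("retain").
    discontinuation_behaviour: Literal["revert", "retain"] = "revert"
    # If False, the CBD-arm benefit is not maintained beyond the freeze cycle:
    # on-treatment occupancy reverts to the usual-care distribution.
    effect_maintained: bool = True

    @model_validator(mode="after")
    def _check(self) -> "ModelConfig":
        validate_age_bands(self.age_bands)
        if set(self.care_hours) != set(FREQ_GROUPS):
            raise ConfigurationError(f"care_hours keys must be {FREQ_GROUPS}")
        if set(self.hcru) != set(FREQ_GROUPS):
            raise ConfigurationError(f"hcru keys must be {FREQ_GROUPS}")
        return self

    # ---- serialization -------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(mode="json"), sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelConfig":
        """Load from a JSON or YAML config file."""
        text = Path(path).read_text()
        if str(path).endswith(".json"):
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        return cls.model_validate(data)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()

    def fictional_parameters(self) -> list[str]:
        """Dotted paths of every FICTIONAL placeholder currently in use."""
        found: list[str] = []

        def walk(node, prefix):
            if isinstance(node, Param):
                if node.fictional:
                    found.append(prefix)
                return
            if isinstance(node, BaseModel):
                for name in type(node).model_fields:
                    walk(getattr(node, name), f"{prefix}.{name}" if prefix else name)
            elif isinstance(node, dict):
                for k, v in node.items():
                    walk(v, f"{prefix}.{k}")
            elif isinstance(node, (list, tuple)):
                for i, v in enumerate(node):
                    walk(v, f"{prefix}.{i}")

        walk(self, "")
        return found


# ---------------------------------------------------------------------------
# Published per-condition defaults
# ---------------------------------------------------------------------------

_AGE_BAND_EDGES = [(2, 5), (6, 11), (12, 17), (18, 55)]

_AGE_BANDS = {
    "LGS": dict(
        props=[(0.13, 0.0003), (0.36, 0.0007), (0.25, 0.0005), (0.26, 0.0005)],
        weights=[(17.9, 0.87), (28.7, 1.34), (51.4, 2.67), (59.7, 2.65)],
    ),
    "DS": dict(
        props=[(0.30, 0.0006), (0.39, 0.0008), (0.29, 0.0006), (0.02, 0.0)],
        weights=[(18.2, 0.53), (30.5, 1.14), (55.0, 2.27), (49.3, 2.27)],
    ),
}

_BASELINE = {
    # mean age (SE); fraction in high-frequency state (SE);
    # low-SFD fraction within {low, high} frequency states (SE)
    "LGS": dict(age=(13.2, 2.63), high=(0.62, 0.0012),
                low_sfd=dict(low=(0.81, 0.0016), high=(0.99, 0.0020))),
    "DS": dict(age=(11.5, 2.30), high=(0.50, 0.0010),
               low_sfd=dict(low=(0.01, 0.0), high=(0.79, 0.0016))),
}

# State utilities from the time-trade-off vignette study.  Low-SFD = few
# seizure-free days (the worse sub-state within each frequency band).
_UTILITIES = {
    "LGS": {
        "SEIZURE_FREE": (0.754, 0.037),
        "LOW_FREQ_LOW_SFD": (0.375, 0.000),
        "LOW_FREQ_HIGH_SFD": (0.565, 0.047),
        "HIGH_FREQ_LOW_SFD": (-0.037, 0.062),
        "HIGH_FREQ_HIGH_SFD": (0.153, 0.063),
    },
    "DS": {
        "SEIZURE_FREE": (0.778, 0.023),
        "LOW_FREQ_LOW_SFD": (0.000, 0.000),
        "LOW_FREQ_HIGH_SFD": (0.690, 0.028),
        "HIGH_FREQ_LOW_SFD": (0.267, 0.053),
        "HIGH_FREQ_HIGH_SFD": (0.437, 0.000),
    },
}

# Weekly hours of care: (child 2-17 mean, SE, adult 18-55 mean, SE)
_CARE_HOURS = {
    "LGS": dict(
        family={"seizure_free": (34.0, 6.8, 6.8, 1.4),
                "low_freq": (67.5, 13.5, 13.5, 2.7),
                "high_freq": (72.1, 14.4, 14.4, 2.9)},
        professional={"seizure_free": (22.7, 4.5, 4.5, 0.9),
                      "low_freq": (45.0, 9.0, 9.0, 1.8),
                      "high_freq": (48.1, 9.6, 9.6, 1.9)},
    ),
    "DS": dict(
        family={"seizure_free": (30.9, 6.2, 6.2, 1.2),
                "low_freq": (61.3, 12.3, 12.3, 2.5),
                "high_freq": (66.1, 13.2, 13.2, 2.6)},
        professional={"seizure_free": (20.6, 4.1, 4.1, 0.8),
                      "low_freq": (40.9, 8.2, 8.2, 1.6),
                      "high_freq": (44.1, 8.8, 8.8, 1.8)},
    ),
}

# usage share (mean, SE) and FICTIONAL daily cost in euros
_ASM_USAGE = {
    "LGS": {
        "clobazam": (1.00, 0.002, 0.50),
        "clonazepam": (0.05, 0.0001, 0.30),
        "levetiracetam": (0.35, 0.0007, 1.20),
        "rufinamide": (0.28, 0.0006, 6.00),
        "stiripentol": (0.00, 0.0, 25.00),
        "topiramate": (0.14, 0.0003, 1.00),
        "valproate_sodium": (0.00, 0.0, 0.40),
        "valproic_acid": (0.24, 0.0005, 0.40),
        "zonisamide": (0.12, 0.0003, 2.50),
    },
    "DS": {
        "clobazam": (1.00, 0.002, 0.50),
        "clonazepam": (0.07, 0.0001, 0.30),
        "levetiracetam": (0.20, 0.0004, 1.20),
        "rufinamide": (0.05, 0.0001, 6.00),
        "stiripentol": (0.44, 0.0009, 25.00),
        "topiramate": (0.22, 0.0004, 1.00),
        "valproate_sodium": (0.22, 0.0004, 0.40),
        "valproic_acid": (0.64, 0.0013, 0.40),
        "zonisamide": (0.11, 0.0002, 2.50),
    },
}

# FICTIONAL per-cycle resource-use probabilities by frequency group
_HCRU = {
    "seizure_free": dict(ed=0.02, nurse=0.10, hosp=0.005, inst=0.04, days=4.0),
    "low_freq": dict(ed=0.12, nurse=0.35, hosp=0.060, inst=0.12, days=4.0),
    "high_freq": dict(ed=0.30, nurse=0.60, hosp=0.150, inst=0.22, days=4.0),
}


def _utility_param(mean: float, se: float) -> Param:
    # utilities that can go negative cannot use a plain beta
    dist = "truncnorm" if mean - 1.96 * se < 0 else "beta"
    return Param(mean=mean, se=se, dist=dist)


def default_utilities(condition_name: str) -> UtilityConfig:
    vals = _UTILITIES[condition_name]
    return UtilityConfig(
        state_utilities={k: _utility_param(m, s) for k, (m, s) in vals.items()}
    )


def default_care_hours(condition_name: str) -> dict[str, CareHoursGroup]:
    spec = _CARE_HOURS[condition_name]
    out = {}
    for group in FREQ_GROUPS:
        fc, fcs, fa, fas = spec["family"][group]
        pc, pcs, pa, pas = spec["professional"][group]
        out[group] = CareHoursGroup(
            family_child=Param(mean=fc, se=fcs, dist="gamma"),
            family_adult=Param(mean=fa, se=fas, dist="gamma"),
            professional_child=Param(mean=pc, se=pcs, dist="gamma"),
            professional_adult=Param(mean=pa, se=pas, dist="gamma"),
        )
    return out


def default_hcru() -> dict[str, HcruGroup]:
    out = {}
    for group in FREQ_GROUPS:
        g = _HCRU[group]
        out[group] = HcruGroup(
            ed_visit=Param(mean=g["ed"], dist="beta", fictional=True),
            nurse_visit=Param(mean=g["nurse"], dist="beta", fictional=True),
            hospitalization=Param(mean=g["hosp"], dist="beta", fictional=True),
            institutionalized=Param(mean=g["inst"], dist="beta", fictional=True),
            hospital_days_per_admission=Param(mean=g["days"], dist="gamma", fictional=True),
        )
    return out


def default_age_bands(condition_name: str) -> list[AgeBand]:
    spec = _AGE_BANDS[condition_name]
    bands = []
    for (lo, hi), (p, ps), (w, ws) in zip(_AGE_BAND_EDGES, spec["props"], spec["weights"]):
        bands.append(
            AgeBand(
                lower_age=lo,
                upper_age=hi,
                proportion=Param(mean=p, se=ps, dist="beta"),
                mean_weight_kg=Param(mean=w, se=ws, dist="gamma"),
            )
        )
    return bands


def default_baseline(condition_name: str) -> BaselineAllocation:
    spec = _BASELINE[condition_name]
    return BaselineAllocation(
        mean_age_years=Param(mean=spec["age"][0], se=spec["age"][1], dist="normal"),
        frequency_split=Param(mean=spec["high"][0], se=spec["high"][1], dist="beta"),
        sfd_split_within_frequency={
            "low": Param(mean=spec["low_sfd"]["low"][0], se=spec["low_sfd"]["low"][1], dist="beta"),
            "high": Param(mean=spec["low_sfd"]["high"][0], se=spec["low_sfd"]["high"][1], dist="beta"),
        },
    )


def default_config(condition_name: str) -> ModelConfig:
    """Base-case configuration for LGS or DS with all published defaults."""
    condition = condition_from_name(condition_name)
    asm = {
        name: (Param(mean=m, se=s, dist="beta"), cost)
        for name, (m, s, cost) in _ASM_USAGE[condition_name].items()
    }
    return ModelConfig(
        condition=condition,
        age_bands=default_age_bands(condition_name),
        baseline=default_baseline(condition_name),
        utilities=default_utilities(condition_name),
        care_hours=default_care_hours(condition_name),
        hcru=default_hcru(),
        costs=CostConfig(asm_usage=asm),
    )


# ---------------------------------------------------------------------------
# Dotted-path overrides (used by the scenario battery and sensitivity stages)
# ---------------------------------------------------------------------------

def apply_overrides(config: ModelConfig, overrides: dict[str, object]) -> ModelConfig:
    """Return a new config with dotted-path overrides applied.

    A path like ``"utilities.state_utilities.SEIZURE_FREE.mean"`` addresses a
    nested field; every path must already exist in the schema (unknown paths
    raise :class:`ConfigurationError`).
    """
    data = config.model_dump(mode="json")
    for path, value in overrides.items():
        parts = path.split(".")
        node = data
        for part in parts[:-1]:
            if isinstance(node, list):
                node = node[int(part)]
            elif isinstance(node, dict) and part in node:
                node = node[part]
            else:
                raise ConfigurationError(f"override path {path!r} not in config schema")
        leaf = parts[-1]
        if isinstance(node, list):
            node[int(leaf)] = value
        elif isinstance(node, dict) and leaf in node:
            node[leaf] = value
        else:
            raise ConfigurationError(f"override path {path!r} not in config schema")
    return ModelConfig.model_validate(data)
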