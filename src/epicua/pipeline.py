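"""End-to-end pipeline: generate inputs, run both arms, cost and compare.

The run is fully deterministic in (config, seed); the manifest records the
config hash so every reported number is traceable.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path

from .config import ModelConfig, default_config
from .cohort_engine import CohortTrace, run_arm
from .economics import CEAResult, incremental
from .outcomes_costing import accrue_costs, accrue_qalys, count_events
from .synthetic_inputs import InputBundle, generate_inputs

from importlib.metadata import version as _pkg_version

try:
    _VERSION = _pkg_version("epicua")
except Exception:  # pragma: no cover - not installed
    _VERSION = "unknown"


@dataclasses.dataclass
class ArmResult:
    trace: CohortTrace
    qalys: float
    costs: dict[str, float]
    events: dict[str, float]


@dataclasses.dataclass
class ConditionResult:
    """Full result for one condition: both arms plus the incremental record."""

    config: ModelConfig
    seed: int
    cbd: ArmResult
    usual_care: ArmResult
    cea: CEAResult

    def summary(self) -> dict:
        return {
            "condition": self.config.condition.name,
            "perspective": self.config.perspective,
            "seed": self.seed,
            "cea": self.cea.to_dict(),
            "events_cbd": self.cbd.events,
            "events_usual_care": self.usual_care.events,
            "costs_cbd": self.cbd.costs,
            "costs_usual_care": self.usual_care.costs,
        }


def evaluate_arm(config: ModelConfig, arm: str, bundle: InputBundle) -> ArmResult:
    trace = run_arm(config, arm, bundle)
    sae_prob = (
        config.costs.sae_prob_cbd.mean if arm == "CBD" else config.costs.sae_prob_usual_care.mean
    )
    return ArmResult(
        trace=trace,
        qalys=accrue_qalys(trace, config, sae_prob=sae_prob),
        costs=accrue_costs(trace, config, arm=arm),
        events=count_events(trace, config),
    )


def run_condition(
    config: ModelConfig, seed: int, bundle: InputBundle | None = None
) -> ConditionResult:
    """Run the whole model for one condition and return the comparison."""
    bundle = bundle or generate_inputs(config, seed)
    cbd = evaluate_arm(config, "CBD", bundle)
    uc = evaluate_arm(config, "USUAL_CARE", bundle)
    cea = incremental(
        cbd.costs["total"], uc.costs["total"], cbd.qalys, uc.qalys,
        wtp=config.settings.wtp_per_qaly,
    )
    return ConditionResult(config=config, seed=seed, cbd=cbd, usual_care=uc, cea=cea)


def build_manifest(
    config: ModelConfig, seed: int, outputs: list[str], scenario: str = "base_case"
) -> dict:
    """Run manifest: config hash, seed, version, timestamps, outputs, and
    every FICTIONAL placeholder in use (so none enters a report silently)."""
    return {
        "config_hash": config.config_hash(),
        "seed": seed,
        "scenario": scenario,
        "package_version": _VERSION,
        "n_cycles": config.settings.n_cycles,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "fictional_parameters": config.fictional_parameters(),
        "outputs": outputs,
    }


def run_full_analysis(
    condition: str,
    seed: int,
    config: ModelConfig | None = None,
    config_path: str | Path | None = None,
    out_dir: str | Path | None = None,
    allow_fictional: bool = True,
) -> ConditionResult:
    """Generate -> trace -> evaluate -> compare, optionally writing reports.

    With ``allow_fictional=False`` the run refuses to proceed while any
    FICTIONAL placeholder parameter is still in use.
    """
    if config is None:
        config = (
            ModelConfig.from_file(config_path) if config_path else default_config(condition)
        )
    if config.condition.name != condition:
        raise ValueError(
            f"config is for {config.condition.name}, but condition {condition} was requested"
        )
    fictional = config.fictional_parameters()
    if fictional and not allow_fictional:
        raise ValueError(
            "refusing to run with FICTIONAL placeholder parameters: "
            + ", ".join(fictional[:5])
            + ("..." if len(fictional) > 5 else "")
        )

    result = run_condition(config, seed)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        for arm_name, arm in (("cbd", result.cbd), ("usual_care", result.usual_care)):
            path = out / f"trace_{condition}_{arm_name}.csv"
            arm.trace.to_dataframe().to_csv(path, index=False)
            written.append(path.name)
        cea_path = out / f"cea_{condition}.json"
        cea_path.write_text(json.dumps(result.summary(), indent=2))
        written.append(cea_path.name)
        manifest = build_manifest(config, seed, written)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return result
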