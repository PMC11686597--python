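"""Incremental cost-effectiveness: ICER with dominance verdicts, and net
monetary benefit."""

from __future__ import annotations

import dataclasses
from typing import Literal

Verdict = Literal["ICER", "DOMINATING", "DOMINATED", "BOUNDARY"]


@dataclasses.dataclass(frozen=True)
class CEAResult:
    """Per-arm discounted totals with the incremental comparison.

    ``icer`` is defined only when ``verdict == "ICER"``; a dominating
    intervention (cheaper, more effective) or dominated one (dearer, less
    effective) has no meaningful ratio.  Exact zeros on either increment give
    the "BOUNDARY" verdict rather than forcing a quadrant.
    """

    cost_intervention: float
    cost_comparator: float
    qaly_intervention: float
    qaly_comparator: float
    delta_cost: float
    delta_qaly: float
    verdict: Verdict
    icer: float | None
    nmb: float
    wtp: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def incremental(
    cost_intervention: float,
    cost_comparator: float,
    qaly_intervention: float,
    qaly_comparator: float,
    wtp: float = 80_000.0,
) -> CEAResult:
    """Incremental analysis of intervention vs comparator.

    The ICER is carried unrounded; presentation layers round to whole
    currency units.
    """
    for v in (cost_intervention, cost_comparator, qaly_intervention, qaly_comparator):
        if not (v == v and abs(v) != float("inf")):
            raise ValueError("incremental analysis requires finite inputs")
    delta_cost = cost_intervention - cost_comparator
    delta_qaly = qaly_intervention - qaly_comparator

    icer: float | None = None
    if delta_cost < 0 and delta_qaly > 0:
        verdict: Verdict = "DOMINATING"
    elif delta_cost > 0 and delta_qaly < 0:
        verdict = "DOMINATED"
    elif delta_cost == 0 or delta_qaly == 0:
        verdict = "BOUNDARY"
    else:
        verdict = "ICER"
        icer = delta_cost / delta_qaly

    return CEAResult(
        cost_intervention=cost_intervention,
        cost_comparator=cost_comparator,
        qaly_intervention=qaly_intervention,
        qaly_comparator=qaly_comparator,
        delta_cost=delta_cost,
        delta_qaly=delta_qaly,
        verdict=verdict,
        icer=icer,
        nmb=net_monetary_benefit(delta_cost, delta_qaly, wtp),
        wtp=wtp,
    )


def net_monetary_benefit(delta_cost: float, delta_qaly: float, wtp: float) -> float:
    """Incremental net monetary benefit ``wtp * dQALY - dCost``; positive iff
    cost-effective at that willingness-to-pay."""
    return wtp * delta_qaly - delta_cost
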