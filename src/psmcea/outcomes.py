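"""Incremental cost-effectiveness results for a pair of strategies.

ICER = (C_int - C_comp) / (E_int - E_comp), in USD per QALY gained.
Dominance uses the weak-inequality convention: the intervention is
dominant when it is no more costly and no less effective (and not
identical), dominated in the mirror case; the ratio is reported only
when neither applies.  Net monetary benefit NMB = WTP * dE - dC gives
the equivalent decision rule at a willingness-to-pay threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

from .economics import CostBreakdown
from .errors import ConfigurationError


@dataclass
class StrategyResult:
    """Absolute discounted outcomes of one strategy."""

    label: str
    cost: float
    life_years: float
    qalys: float
    breakdown: Optional[CostBreakdown] = None

    def validate(self) -> "StrategyResult":
        if self.cost < 0:
            raise ConfigurationError("strategy cost must be >= 0")
        if self.qalys > self.life_years + 1e-9:
            raise ConfigurationError("QALYs cannot exceed life-years with utilities <= 1")
        return self


@dataclass
class CEResult:
    intervention: str
    comparator: str
    delta_cost: float
    delta_effect: float
    icer: Optional[float]
    status: str  # "icer" | "dominant" | "dominated" | "equivalent"
    wtp: float
    nmb: float
    cost_effective: bool


def icer(intervention: StrategyResult, comparator: StrategyResult, wtp: float) -> CEResult:
    """Incremental comparison of two strategies at a WTP threshold."""
    if wtp < 0:
        raise ConfigurationError("WTP must be >= 0")
    d_cost = intervention.cost - comparator.cost
    d_eff = intervention.qalys - comparator.qalys

    if d_cost == 0.0 and d_eff == 0.0:
        status, ratio = "equivalent", None
    elif d_cost <= 0.0 and d_eff >= 0.0:
        status, ratio = "dominant", None
    elif d_cost >= 0.0 and d_eff <= 0.0:
        status, ratio = "dominated", None
    else:
        status = "icer"
        ratio = d_cost / d_eff

    nmb = wtp * d_eff - d_cost
    cost_effective = status == "dominant" or (
        status == "icer" and d_eff > 0 and ratio is not None and ratio < wtp
    )
    return CEResult(
        intervention=intervention.label,
        comparator=comparator.label,
        delta_cost=d_cost,
        delta_effect=d_eff,
        icer=ratio,
        status=status,
        wtp=wtp,
        nmb=nmb,
        cost_effective=cost_effective,
    )


def net_monetary_benefit(result: CEResult, wtp: float) -> float:
    """NMB = WTP * dE - dC at an arbitrary threshold."""
    if wtp < 0:
        raise ConfigurationError("WTP must be >= 0")
    return wtp * result.delta_effect - result.delta_cost


def round_currency(value: float) -> str:
    """Half-up rounding to cents for display/serialisation."""
    return str(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
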