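"""Cost and QALY accrual over a partitioned-survival state trace.

Cost categories follow the payer-perspective decomposition used in
oncology cost-effectiveness models: first-line drug acquisition,
infusion administration, one-time grade>=3 adverse-event management,
routine follow-up, weighted subsequent (second-line) systemic therapy,
best supportive care in progressive disease, and a one-time end-of-life
expense applied to incident deaths.  Utilities weight state occupancy
into QALYs; adverse-event disutilities are charged once in the first
cycle.  All flows are discounted at an annual rate with monthly
compounding exponent t/12.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import ConfigurationError, DataError
from .psm import StateTrace, _accrual_weights, cycle_discount_factors

#: days per model month (365.25 / 12), used for daily-dosed oral drugs
MONTH_DAYS = 365.25 / 12.0
WEEKS_PER_MONTH = MONTH_DAYS / 7.0

COST_CATEGORIES = (
    "drug", "administration", "adverse_events", "followup",
    "subsequent", "bsc", "end_of_life",
)


@dataclass(frozen=True)
class DrugComponent:
    """One drug within a regimen.

    ``dose_rule`` is one of ``per_kg`` (mg per kg per administration),
    ``flat`` (mg per administration) or ``daily`` (mg per day, oral).
    Interval applies to administered (IV) rules; ``max_doses`` caps the
    cumulative number of administrations (induction), and
    ``start_month`` delays the component (maintenance).  ``fraction``
    scales the component for blended comparator arms (the share of
    patients receiving this drug).
    """

    drug: str
    dose_rule: str
    dose: float
    interval_weeks: Optional[float] = None
    max_doses: Optional[int] = None
    start_month: float = 0.0
    fraction: float = 1.0
    route: str = "iv"

    def __post_init__(self) -> None:
        if self.dose_rule not in ("per_kg", "flat", "daily"):
            raise ConfigurationError(f"unknown dose rule {self.dose_rule!r}")
        if self.dose <= 0:
            raise ConfigurationError("dose must be positive")
        if self.dose_rule != "daily" and (self.interval_weeks is None or self.interval_weeks <= 0):
            raise ConfigurationError("administered components need a positive interval")
        if not 0.0 <= self.fraction <= 1.0:
            raise ConfigurationError("fraction must lie in [0, 1]")


@dataclass(frozen=True)
class DrugSchedule:
    components: tuple[DrugComponent, ...]

    def __post_init__(self) -> None:
        if not self.components:
            raise ConfigurationError("schedule needs >= 1 component")


@dataclass(frozen=True)
class AdverseEvent:
    """Grade >=3 event with per-arm incidence, management cost, disutility."""

    name: str
    incidence: dict  # arm label -> probability
    unit_cost: float
    disutility: float

    def __post_init__(self) -> None:
        if self.unit_cost < 0 or self.disutility < 0:
            raise ConfigurationError("AE cost and disutility must be >= 0")
        for arm, p in self.incidence.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"AE incidence for {arm} outside [0, 1]")


@dataclass(frozen=True)
class SubsequentTherapy:
    name: str
    proportion: float
    monthly_cost: float


@dataclass
class EconParams:
    """Complete economic parameter set for one country perspective."""

    country: str
    drug_prices: dict            # drug -> USD per mg
    admin_cost_per_infusion: float
    adverse_events: list         # of AdverseEvent
    followup_cost_per_cycle: float
    subsequent_therapies: dict   # arm -> list[SubsequentTherapy]
    bsc_cost_per_cycle: float
    end_of_life_cost: float
    utilities: dict              # state -> utility
    discount_rate: float
    wtp: float
    mean_weight_kg: float
    prop_male: float = 0.5
    subsequent_cost_scale: dict = field(default_factory=dict)  # arm -> multiplier
    currency: str = "USD-2024"
    synthetic: bool = False

    def validate(self) -> "EconParams":
        for state in ("pfs", "pfs2", "pd", "death"):
            u = self.utilities.get(state)
            if u is None or not 0.0 <= u <= 1.0:
                raise ConfigurationError(f"utility for state {state!r} missing or outside [0, 1]")
        for name, price in self.drug_prices.items():
            if price < 0:
                raise ConfigurationError(f"negative price for {name}")
        for value, label in (
            (self.admin_cost_per_infusion, "administration"),
            (self.followup_cost_per_cycle, "follow-up"),
            (self.bsc_cost_per_cycle, "BSC"),
            (self.end_of_life_cost, "end-of-life"),
        ):
            if value < 0:
                raise ConfigurationError(f"negative {label} cost")
        if self.discount_rate < 0:
            raise ConfigurationError("discount rate must be >= 0")
        if self.mean_weight_kg <= 0:
            raise ConfigurationError("mean body weight must be positive")
        return self


@dataclass
class CostBreakdown:
    """Discounted totals per cost category; the grand total is their sum."""

    categories: dict

    @property
    def total(self) -> float:
        return float(sum(self.categories.values()))

    def __post_init__(self) -> None:
        for cat in COST_CATEGORIES:
            self.categories.setdefault(cat, 0.0)
        for cat, v in self.categories.items():
            if v < -1e-9:
                raise DataError(f"negative cost total for category {cat}")


def discount_factor(rate: float, t: float) -> float:
    """(1 + r)^(-t/12) for cycle index t (months)."""
    if rate < 0:
        raise ConfigurationError("discount rate must be >= 0")
    return float((1.0 + rate) ** (-t / 12.0))


def _doses_in_cycle(component: DrugComponent, cycle_index: int) -> float:
    """Administrations of an IV component falling in cycle (t-1, t],
    under continuous-rate accounting with a cumulative cap."""
    rate = WEEKS_PER_MONTH / component.interval_weeks  # administrations/month
    lo = max(0.0, (cycle_index - 1) - component.start_month)
    hi = max(0.0, cycle_index - component.start_month)
    cum_lo, cum_hi = rate * lo, rate * hi
    if component.max_doses is not None:
        cum_lo = min(cum_lo, component.max_doses)
        cum_hi = min(cum_hi, component.max_doses)
    return cum_hi - cum_lo


def _active_fraction(component: DrugComponent, cycle_index: int) -> float:
    """Share of cycle (t-1, t] during which a daily component is active."""
    lo, hi = cycle_index - 1.0, float(cycle_index)
    start = component.start_month
    return max(0.0, hi - max(lo, start)) / (hi - lo)


def drug_cost_per_cycle(schedule: DrugSchedule, weight_kg: float,
                        prices: dict, cycle_index: int) -> float:
    """Acquisition cost of one person-cycle on the regimen (USD).

    Per-kg and flat IV doses are multiplied by the administrations
    falling in the cycle; daily oral doses consume dose * 365.25/12 mg
    per fully active cycle.  Prices are USD per mg.
    """
    if weight_kg <= 0:
        raise ConfigurationError("weight must be positive")
    if cycle_index < 1:
        raise ConfigurationError("cycle index starts at 1")
    total = 0.0
    for comp in schedule.components:
        if comp.drug not in prices:
            raise ConfigurationError(f"no price configured for {comp.drug!r}")
        price = prices[comp.drug]
        if comp.dose_rule == "daily":
            mg = comp.dose * MONTH_DAYS * _active_fraction(comp, cycle_index)
        else:
            mg_per_dose = comp.dose * weight_kg if comp.dose_rule == "per_kg" else comp.dose
            mg = mg_per_dose * _doses_in_cycle(comp, cycle_index)
        total += comp.fraction * mg * price
    return total


def infusions_per_cycle(schedule: DrugSchedule, cycle_index: int) -> float:
    """Expected number of infusion visits in the cycle (IV components only).

    Components given on the same day (equal interval and start, e.g. a
    q3w doublet) are counted as a single visit.
    """
    visits: dict[tuple, float] = {}
    for comp in schedule.components:
        if comp.route != "iv" or comp.dose_rule == "daily":
            continue
        key = (comp.interval_weeks, comp.start_month, comp.max_doses)
        visits[key] = max(visits.get(key, 0.0),
                          comp.fraction * _doses_in_cycle(comp, cycle_index))
    return sum(visits.values())


def weighted_subsequent_cost(therapies: list, bsc_cost: float) -> float:
    """Weighted mean monthly cost of subsequent systemic therapy.

    The share of patients not covered by any listed regimen is priced at
    the best-supportive-care rate.
    """
    total_p = 0.0
    cost = 0.0
    for th in therapies:
        if th.proportion < 0:
            raise ConfigurationError(f"negative proportion for {th.name}")
        if th.monthly_cost < 0:
            raise ConfigurationError(f"negative monthly cost for {th.name}")
        total_p += th.proportion
        cost += th.proportion * th.monthly_cost
    if total_p > 1.0 + 1e-9:
        raise ConfigurationError("subsequent-therapy proportions sum above 1")
    return cost + max(0.0, 1.0 - total_p) * bsc_cost


def accumulate(trace: StateTrace, params: EconParams, schedule: DrugSchedule,
               arm: str, pfs_only_accrual: bool = False,
               include_ae_disutility: bool = True):
    """Discounted (CostBreakdown, QALYs, life-years) for one strategy arm.

    First-line drug and administration costs follow PFS occupancy
    (treat-to-progression); subsequent therapy follows PFS2; BSC follows
    PD; follow-up accrues over all alive states.  Adverse-event costs
    and disutilities are one-time first-cycle quantities; the
    end-of-life cost multiplies incident deaths in each cycle.  With
    ``pfs_only_accrual`` both costs and QALYs accrue in the PFS state
    only (the PFS-only scenario).
    """
    params.validate()
    n = trace.n_cycles
    r = params.discount_rate
    df = cycle_discount_factors(r, n)[1:]  # cycles 1..n
    hcc = trace.half_cycle_correction

    occ_pfs = _accrual_weights(trace.pfs, hcc)
    if pfs_only_accrual:
        occ_pfs2 = np.zeros(n)
        occ_pd = np.zeros(n)
        occ_alive = occ_pfs
    else:
        occ_pfs2 = _accrual_weights(trace.pfs2, hcc)
        occ_pd = _accrual_weights(trace.pd, hcc)
        occ_alive = occ_pfs + occ_pfs2 + occ_pd

    cycles = np.arange(1, n + 1)
    drug_cc = np.array(
        [drug_cost_per_cycle(schedule, params.mean_weight_kg, params.drug_prices, t)
         for t in cycles]
    )
    admin_cc = np.array(
        [infusions_per_cycle(schedule, t) * params.admin_cost_per_infusion for t in cycles]
    )
    sub_scale = params.subsequent_cost_scale.get(arm, 1.0)
    sub_cc = sub_scale * weighted_subsequent_cost(
        params.subsequent_therapies.get(arm, []), params.bsc_cost_per_cycle
    )

    ae_cost = 0.0
    ae_disutility = 0.0
    for ae in params.adverse_events:
        inc = ae.incidence.get(arm, 0.0)
        ae_cost += inc * ae.unit_cost
        ae_disutility += inc * ae.disutility

    cats = {
        "drug": float(np.sum(occ_pfs * drug_cc * df)),
        "administration": float(np.sum(occ_pfs * admin_cc * df)),
        "adverse_events": ae_cost * discount_factor(r, 1),
        "followup": params.followup_cost_per_cycle * float(np.sum(occ_alive * df)),
        "subsequent": sub_cc * float(np.sum(occ_pfs2 * df)),
        "bsc": params.bsc_cost_per_cycle * float(np.sum(occ_pd * df)),
        "end_of_life": params.end_of_life_cost
        * float(np.sum(trace.incident_deaths[1:] * df)),
    }
    breakdown = CostBreakdown(categories=cats)

    u = params.utilities
    qaly = (
        u["pfs"] * float(np.sum(occ_pfs * df))
        + u["pfs2"] * float(np.sum(occ_pfs2 * df))
        + u["pd"] * float(np.sum(occ_pd * df))
    ) / 12.0
    if include_ae_disutility:
        qaly -= ae_disutility * (1.0 / 12.0) * discount_factor(r, 1)
    ly = float(np.sum(occ_alive * df) / 12.0)
    return breakdown, qaly, ly


# ---------------------------------------------------------------------------
# regimen construction for the modelled comparison
# ---------------------------------------------------------------------------

ARM_TREAT = "NIVO+IPI"
ARM_CONTROL = "LEN/SOR"

#: induction length of the q3w doublet: 4 doses, 3 weeks apart
_INDUCTION_END_MONTH = 4 * 3.0 / WEEKS_PER_MONTH


def nivo_ipi_schedule() -> DrugSchedule:
    """Nivolumab 1 mg/kg + ipilimumab 3 mg/kg q3w for up to four doses,
    then maintenance nivolumab 480 mg flat q4w."""
    return DrugSchedule(
        components=(
            DrugComponent("nivolumab", "per_kg", 1.0, interval_weeks=3.0, max_doses=4),
            DrugComponent("ipilimumab", "per_kg", 3.0, interval_weeks=3.0, max_doses=4),
            DrugComponent("nivolumab", "flat", 480.0, interval_weeks=4.0,
                          start_month=_INDUCTION_END_MONTH),
        )
    )


def comparator_schedule(weight_kg: float, comparator: str = "blend",
                        lenvatinib_share: float = 0.75) -> DrugSchedule:
    """Oral comparator arm: lenvatinib 8 mg/day (<60 kg) or 12 mg/day
    (>=60 kg), or sorafenib 400 mg twice daily, or a blended mix."""
    len_dose = 8.0 if weight_kg < 60.0 else 12.0
    lenva = DrugComponent("lenvatinib", "daily", len_dose, route="oral")
    sora = DrugComponent("sorafenib", "daily", 800.0, route="oral")
    if comparator == "lenvatinib":
        return DrugSchedule(components=(lenva,))
    if comparator == "sorafenib":
        return DrugSchedule(components=(sora,))
    if comparator == "blend":
        if not 0.0 <= lenvatinib_share <= 1.0:
            raise ConfigurationError("lenvatinib share must lie in [0, 1]")
        return DrugSchedule(
            components=(
                replace(lenva, fraction=lenvatinib_share),
                replace(sora, fraction=1.0 - lenvatinib_share),
            )
        )
    raise ConfigurationError(f"unknown comparator {comparator!r}")
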