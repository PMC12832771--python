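"""End-to-end orchestration: synthetic or digitized inputs through
reconstruction, parametric fitting, model averaging, the partitioned
survival model, economics, and the uncertainty analyses.

The central object is the survivor-grid bundle ``grids[arm][endpoint]``
(monthly S(t) out to the extrapolation horizon).  Economic evaluation is
cheap relative to fitting, so sensitivity analyses re-run only the
economics stage through ``make_model_fn`` while survival stays at base —
survival-parameter uncertainty is deliberately not resampled.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import synthetic as syn
from .economics import (
    ARM_CONTROL,
    ARM_TREAT,
    EconParams,
    accumulate,
    comparator_schedule,
    nivo_ipi_schedule,
)
from .errors import ConfigurationError
from .outcomes import CEResult, StrategyResult, icer
from .psm import PSMConfig, compute_occupancy
from .reconstruct import reconstruct_ipd
from .survfit import akaike_weights, fit_all_families, goodness_of_fit_report, survivor_grid
from .uncertainty import (
    ParamRange,
    PSAParam,
    PSASpec,
    ceac,
    one_way_sa,
    pct20,
    price_threshold,
    psa,
    two_way_sa,
    validate_scenario,
    WTP_GRID_CHINA,
    WTP_GRID_US,
)

EXTRAPOLATION_CYCLES = 240  # 20-year horizon at monthly cycles


@dataclass
class RunConfig:
    """Everything needed for one reproducible pipeline run."""

    country: str = "US"
    population: str = "ITT"
    seed: int = 1
    scenario: Optional[syn.TrialScenario] = None   # defaults per population
    econ: Optional[EconParams] = None              # defaults per country
    psm: PSMConfig = field(default_factory=PSMConfig)
    comparator: str = "blend"
    lenvatinib_share: float = 0.75
    analyses: tuple = ("base",)
    n_psa_draws: int = 1000
    outdir: str = "results"
    log_level: str = "INFO"

    def validate(self) -> "RunConfig":
        if self.country not in ("US", "China"):
            raise ConfigurationError("country must be 'US' or 'China'")
        if self.population not in ("ITT", "China-subgroup"):
            raise ConfigurationError("population must be 'ITT' or 'China-subgroup'")
        known = {"base", "owsa", "twoway", "psa", "threshold", "scenarios"}
        unknown = set(self.analyses) - known
        if unknown:
            raise ConfigurationError(f"unknown analyses: {sorted(unknown)}")
        self.psm.validate()
        return self


@dataclass
class SurvivalStage:
    """Fitted survivor machinery for both arms and endpoints."""

    curves: dict
    risk_tables: dict
    reconstructed: dict
    ensembles: dict
    grids: dict          # arm -> endpoint -> np.ndarray over 0..EXTRAPOLATION_CYCLES
    gof: dict


def run_survival_stage(scenario: syn.TrialScenario, seed: int,
                       n_cycles: int = EXTRAPOLATION_CYCLES) -> SurvivalStage:
    """Simulate the trial, publish its KM curves, reconstruct pseudo-IPD,
    fit the five families, and average them into survivor grids."""
    ipd = syn.simulate_ipd(scenario, seed)
    curves, risks, recs, ensembles, grids, gof = {}, {}, {}, {}, {}, {}
    for arm in scenario.arm_names:
        curves[arm], risks[arm], recs[arm], ensembles[arm] = {}, {}, {}, {}
        grids[arm], gof[arm] = {}, {}
        for endpoint in syn.ENDPOINTS:
            subset = ipd[(ipd["arm"] == arm) & (ipd["endpoint"] == endpoint)]
            curve, risk = syn.km_from_ipd(subset, scenario.risk_table_interval)
            rec = reconstruct_ipd(curve, risk)
            models = fit_all_families(rec)
            ens = akaike_weights(models, endpoint=endpoint, arm=arm)
            curves[arm][endpoint] = curve
            risks[arm][endpoint] = risk
            recs[arm][endpoint] = rec
            ensembles[arm][endpoint] = ens
            grids[arm][endpoint] = survivor_grid(ens, n_cycles)
            gof[arm][endpoint] = goodness_of_fit_report(ens, curve)
    return SurvivalStage(curves, risks, recs, ensembles, grids, gof)


# ---------------------------------------------------------------------------
# economic evaluation over fixed survivor grids
# ---------------------------------------------------------------------------

_SCALAR_PATHS = {
    "admin_cost": "admin_cost_per_infusion",
    "followup_cost": "followup_cost_per_cycle",
    "bsc_cost": "bsc_cost_per_cycle",
    "eol_cost": "end_of_life_cost",
    "discount_rate": "discount_rate",
    "weight_kg": "mean_weight_kg",
    "prop_male": "prop_male",
}


def apply_overrides(econ: EconParams, psm_cfg: PSMConfig, overrides: dict):
    """Return copies of the parameter objects with dotted-path overrides
    applied; unknown paths raise :class:`ConfigurationError`."""
    econ = dataclasses.replace(
        econ,
        drug_prices=dict(econ.drug_prices),
        utilities=dict(econ.utilities),
        adverse_events=list(econ.adverse_events),
        subsequent_cost_scale=dict(econ.subsequent_cost_scale),
    )
    psm_cfg = dataclasses.replace(psm_cfg)
    for path, value in overrides.items():
        if path in _SCALAR_PATHS:
            setattr(econ, _SCALAR_PATHS[path], float(value))
        elif path == "pfs2_exit_rate":
            psm_cfg.pfs2_exit_rate = float(value)
        elif path.startswith("price."):
            drug = path.split(".", 1)[1]
            if drug not in econ.drug_prices:
                raise ConfigurationError(f"unknown drug {drug!r} in override {path!r}")
            econ.drug_prices[drug] = float(value)
        elif path.startswith("utility."):
            state = path.split(".", 1)[1]
            if state not in econ.utilities:
                raise ConfigurationError(f"unknown state {state!r} in override {path!r}")
            econ.utilities[state] = float(value)
        elif path.startswith("ae_cost."):
            name = path.split(".", 1)[1]
            econ.adverse_events = [
                dataclasses.replace(ae, unit_cost=float(value)) if ae.name == name else ae
                for ae in econ.adverse_events
            ]
        elif path.startswith("ae_disutility."):
            name = path.split(".", 1)[1]
            econ.adverse_events = [
                dataclasses.replace(ae, disutility=float(value)) if ae.name == name else ae
                for ae in econ.adverse_events
            ]
        elif path.startswith("subsequent_scale."):
            arm = path.split(".", 1)[1]
            econ.subsequent_cost_scale[arm] = float(value)
        else:
            raise ConfigurationError(f"unknown override path {path!r}")
    return econ, psm_cfg


def evaluate_strategies(grids: dict, econ: EconParams, psm_cfg: PSMConfig,
                        comparator: str = "blend", lenvatinib_share: float = 0.75,
                        pfs_only_accrual: bool = False,
                        include_ae_disutility: bool = True,
                        wtp: Optional[float] = None):
    """PSM + economics for both arms; returns (treat, control, CEResult)."""
    schedules = {
        ARM_TREAT: nivo_ipi_schedule(),
        ARM_CONTROL: comparator_schedule(econ.mean_weight_kg, comparator, lenvatinib_share),
    }
    results = {}
    for arm in (ARM_TREAT, ARM_CONTROL):
        trace = compute_occupancy(grids[arm]["PFS"], grids[arm]["OS"], psm_cfg)
        breakdown, qaly, ly = accumulate(
            trace, econ, schedules[arm], arm,
            pfs_only_accrual=pfs_only_accrual,
            include_ae_disutility=include_ae_disutility,
        )
        results[arm] = StrategyResult(
            label=arm, cost=breakdown.total, life_years=ly, qalys=qaly,
            breakdown=breakdown,
        ).validate()
    ce = icer(results[ARM_TREAT], results[ARM_CONTROL], wtp if wtp is not None else econ.wtp)
    return results[ARM_TREAT], results[ARM_CONTROL], ce


def make_model_fn(grids: dict, econ: EconParams, psm_cfg: PSMConfig,
                  comparator: str = "blend", lenvatinib_share: float = 0.75,
                  **eval_kwargs):
    """Closure re-running the economic model under parameter overrides,
    with survival held at base (the deterministic model for SA/PSA)."""

    def model_fn(overrides: dict) -> CEResult:
        econ2, psm2 = apply_overrides(econ, psm_cfg, overrides)
        _, _, ce = evaluate_strategies(
            grids, econ2, psm2, comparator=comparator,
            lenvatinib_share=lenvatinib_share, **eval_kwargs,
        )
        return ce

    return model_fn


# ---------------------------------------------------------------------------
# default analysis specifications
# ---------------------------------------------------------------------------

def default_ranges(econ: EconParams) -> list:
    """One-way ranges: ±20% for unit costs and utilities (utilities capped
    at 1), 0 to max(8%, base) for the discount rate."""
    ranges = []
    for drug, price in sorted(econ.drug_prices.items()):
        ranges.append(pct20(f"price.{drug}", price))
    for path in ("admin_cost", "followup_cost", "bsc_cost", "eol_cost"):
        base = getattr(econ, _SCALAR_PATHS[path])
        if base > 0:
            ranges.append(pct20(path, base))
    for state in ("pfs", "pfs2", "pd"):
        u = econ.utilities[state]
        ranges.append(ParamRange(f"utility.{state}", u, 0.8 * u, min(1.0, 1.2 * u)))
    for ae in econ.adverse_events:
        if ae.unit_cost > 0:
            ranges.append(pct20(f"ae_cost.{ae.name}", ae.unit_cost))
    for arm in (ARM_TREAT, ARM_CONTROL):
        ranges.append(pct20(f"subsequent_scale.{arm}", 1.0))
    r = econ.discount_rate
    ranges.append(ParamRange("discount_rate", r, 0.0, max(0.08, r), source="custom"))
    ranges.append(pct20("weight_kg", econ.mean_weight_kg))
    ranges.append(pct20("prop_male", econ.prop_male))
    return ranges


def default_psa_params(econ: EconParams) -> list:
    """Gamma on every cost-type parameter, beta on utilities."""
    params = []
    for drug, price in sorted(econ.drug_prices.items()):
        params.append(PSAParam(f"price.{drug}", price, "gamma"))
    for path in ("admin_cost", "followup_cost", "bsc_cost", "eol_cost"):
        base = getattr(econ, _SCALAR_PATHS[path])
        if base > 0:
            params.append(PSAParam(path, base, "gamma"))
    for ae in econ.adverse_events:
        if ae.unit_cost > 0:
            params.append(PSAParam(f"ae_cost.{ae.name}", ae.unit_cost, "gamma"))
    for state in ("pfs", "pfs2", "pd"):
        u = econ.utilities[state]
        params.append(PSAParam(f"utility.{state}", u, "beta", sd=0.05))
    return params


def run_scenario(grids_by_population: dict, econ: EconParams, psm_cfg: PSMConfig,
                 scenario: dict, base_population: str = "ITT",
                 lenvatinib_share: float = 0.75,
                 alt_pfs_grids: Optional[dict] = None):
    """Re-run the model under one scenario definition.

    ``grids_by_population`` maps population labels to survivor-grid
    bundles.  ``alt_pfs_grids`` (arm -> grid) supplies the alternative
    PFS source when ``pfs_source='investigator'`` is requested.
    """
    validate_scenario(scenario)
    population = scenario.get("population", base_population)
    if population not in grids_by_population:
        raise ConfigurationError(f"no survivor grids for population {population!r}")
    grids = {arm: dict(eps) for arm, eps in grids_by_population[population].items()}
    if scenario.get("pfs_source") == "investigator":
        if alt_pfs_grids is None:
            raise ConfigurationError("no investigator-assessed PFS grids configured")
        for arm, grid in alt_pfs_grids.items():
            grids[arm]["PFS"] = grid
    psm_cfg = dataclasses.replace(psm_cfg)
    horizon = scenario.get("horizon_years")
    if horizon is not None:
        psm_cfg.n_cycles = int(horizon * 12)
    treat, control, ce = evaluate_strategies(
        grids, econ, psm_cfg,
        comparator=scenario.get("comparator", "blend"),
        lenvatinib_share=lenvatinib_share,
        pfs_only_accrual=bool(scenario.get("pfs_only_accrual", False)),
        include_ae_disutility=not scenario.get("exclude_ae_disutility", False),
    )
    return treat, control, ce


@dataclass
class PipelineResult:
    config: RunConfig
    survival: SurvivalStage
    treat: StrategyResult
    control: StrategyResult
    base_case: CEResult
    tornado: Optional[pd.DataFrame] = None
    twoway: Optional[pd.DataFrame] = None
    psa_draws: Optional[pd.DataFrame] = None
    ceac_table: Optional[pd.DataFrame] = None
    thresholds: Optional[list] = None
    scenario_table: Optional[pd.DataFrame] = None


def run_analyses(config: RunConfig, stage: SurvivalStage) -> PipelineResult:
    """Base case plus whichever analyses the config requests."""
    config.validate()
    econ = config.econ if config.econ is not None else syn.make_parameter_set(config.country)
    treat, control, base = evaluate_strategies(
        stage.grids, econ, config.psm,
        comparator=config.comparator, lenvatinib_share=config.lenvatinib_share,
    )
    result = PipelineResult(config, stage, treat, control, base)
    model_fn = make_model_fn(
        stage.grids, econ, config.psm,
        comparator=config.comparator, lenvatinib_share=config.lenvatinib_share,
    )

    if "owsa" in config.analyses:
        result.tornado = one_way_sa(model_fn, default_ranges(econ))
    if "twoway" in config.analyses:
        result.twoway = two_way_sa(
            model_fn,
            pct20("price.nivolumab", econ.drug_prices["nivolumab"]),
            pct20("price.ipilimumab", econ.drug_prices["ipilimumab"]),
            grid_size=9,
        )
    if "psa" in config.analyses:
        spec = PSASpec(default_psa_params(econ), n_draws=config.n_psa_draws,
                       seed=config.seed)
        result.psa_draws = psa(model_fn, spec)
        grid = WTP_GRID_US if config.country == "US" else WTP_GRID_CHINA
        result.ceac_table = ceac(result.psa_draws, grid)
    if "threshold" in config.analyses:
        base_prices = {
            "price.nivolumab": econ.drug_prices["nivolumab"],
            "price.ipilimumab": econ.drug_prices["ipilimumab"],
        }
        result.thresholds = [
            price_threshold(model_fn, paths, econ.wtp, base_prices=base_prices)
            for paths in (
                ["price.nivolumab"],
                ["price.ipilimumab"],
                ["price.nivolumab", "price.ipilimumab"],
            )
        ]
    if "scenarios" in config.analyses:
        grids_by_pop = {config.population: stage.grids}
        rows = []
        scenarios = [
            {"exclude_ae_disutility": True},
            {"horizon_years": 4},
            {"horizon_years": 5},
            {"horizon_years": 10},
            {"pfs_only_accrual": True},
            {"comparator": "lenvatinib"},
            {"comparator": "sorafenib"},
        ]
        for sc in scenarios:
            t, c, ce = run_scenario(
                grids_by_pop, econ, config.psm, sc,
                base_population=config.population,
                lenvatinib_share=config.lenvatinib_share,
            )
            rows.append(
                {
                    "scenario": str(sc),
                    "cost_intervention": t.cost,
                    "cost_comparator": c.cost,
                    "delta_cost": ce.delta_cost,
                    "qaly_intervention": t.qalys,
                    "qaly_comparator": c.qalys,
                    "delta_qaly": ce.delta_effect,
                    "icer": ce.icer if ce.icer is not None else float("nan"),
                    "status": ce.status,
                }
            )
        result.scenario_table = pd.DataFrame(rows)
    return result


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Full run: synthetic trial (or configured scenario) through every
    requested analysis.  Disk output is handled by :mod:`psmcea.io`."""
    config.validate()
    scenario = config.scenario if config.scenario is not None else syn.default_scenario(
        config.population
    )
    stage = run_survival_stage(scenario, config.seed, config.psm.n_cycles
                               if config.psm.n_cycles > EXTRAPOLATION_CYCLES
                               else EXTRAPOLATION_CYCLES)
    return run_analyses(config, stage)
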