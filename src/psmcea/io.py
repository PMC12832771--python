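"""File formats: curve/risk/IPD CSVs, YAML configuration, result bundles.

All tabular outputs are plain CSV with header rows.  Currency columns
are serialised as exact decimal strings rounded half-up to cents;
probabilities keep full double precision.  Every result bundle carries a
JSON manifest with the configuration hash, seed and package version so
a run can be reproduced bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .economics import EconParams, AdverseEvent, SubsequentTherapy
from .errors import DataError, ConfigurationError
from .outcomes import round_currency
from .pipeline import PipelineResult, RunConfig
from .psm import PSMConfig
from .reconstruct import DigitizedCurve, ReconstructedIPD, RiskTable
from .synthetic import EndpointTruth, TrialScenario

CURVE_COLUMNS = ["time_months", "survival"]
RISK_COLUMNS = ["time_months", "n_at_risk"]
IPD_COLUMNS = ["time_months", "event"]


def _check_header(df: pd.DataFrame, expected: list, path) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise DataError(
            f"{path}: missing columns {missing}; expected header {expected}"
        )


def _check_numeric(df: pd.DataFrame, cols: list, path) -> pd.DataFrame:
    for col in cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise DataError(
                f"{path}: non-numeric value in column {col!r} at data line "
                f"{int(bad[0]) + 2}"
            )
        if coerced.isna().any():
            raise DataError(f"{path}: empty value in column {col!r}")
        df[col] = coerced
    return df


def read_curve_csv(path, endpoint: str = "", arm: str = "") -> DigitizedCurve:
    p = Path(path)
    if not p.exists():
        raise DataError(f"file not found: {path}")
    df = pd.read_csv(p)
    _check_header(df, CURVE_COLUMNS, path)
    df = _check_numeric(df, CURVE_COLUMNS, path)
    curve = DigitizedCurve(
        df["time_months"].to_numpy(), df["survival"].to_numpy(),
        endpoint=endpoint, arm=arm,
    )
    return curve.validate()


def write_curve_csv(curve: DigitizedCurve, path) -> None:
    pd.DataFrame({"time_months": curve.times, "survival": curve.survival}).to_csv(
        path, index=False
    )


def read_risk_csv(path) -> RiskTable:
    p = Path(path)
    if not p.exists():
        raise DataError(f"file not found: {path}")
    df = pd.read_csv(p)
    _check_header(df, RISK_COLUMNS, path)
    df = _check_numeric(df, RISK_COLUMNS, path)
    return RiskTable(df["time_months"].to_numpy(), df["n_at_risk"].to_numpy()).validate()


def write_risk_csv(risk: RiskTable, path) -> None:
    pd.DataFrame({"time_months": risk.times, "n_at_risk": risk.n_at_risk}).to_csv(
        path, index=False
    )


def read_ipd_csv(path) -> pd.DataFrame:
    p = Path(path)
    if not p.exists():
        raise DataError(f"file not found: {path}")
    df = pd.read_csv(p)
    _check_header(df, IPD_COLUMNS, path)
    return _check_numeric(df, IPD_COLUMNS, path)


def write_ipd_csv(ipd, path, diagnostics_path=None) -> None:
    data = ipd.data if isinstance(ipd, ReconstructedIPD) else ipd
    data.to_csv(path, index=False)
    if diagnostics_path is not None and isinstance(ipd, ReconstructedIPD):
        Path(diagnostics_path).write_text(json.dumps(ipd.diagnostics, indent=2))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def econ_to_dict(econ: EconParams) -> dict:
    d = dataclasses.asdict(econ)
    return d


def econ_from_dict(d: dict) -> EconParams:
    d = dict(d)
    d["adverse_events"] = [AdverseEvent(**ae) for ae in d.get("adverse_events", [])]
    d["subsequent_therapies"] = {
        arm: [SubsequentTherapy(**th) for th in ths]
        for arm, ths in d.get("subsequent_therapies", {}).items()
    }
    return EconParams(**d).validate()


def write_econ_yaml(econ: EconParams, path) -> None:
    Path(path).write_text(yaml.safe_dump(econ_to_dict(econ), sort_keys=True))


def read_econ_yaml(path) -> EconParams:
    return econ_from_dict(yaml.safe_load(Path(path).read_text()))


def scenario_from_dict(d: dict) -> TrialScenario:
    d = dict(d)
    if "endpoint_truth" in d:
        d["endpoint_truth"] = {
            arm: {ep: EndpointTruth(**t) for ep, t in eps.items()}
            for arm, eps in d["endpoint_truth"].items()
        }
    if "arm_names" in d:
        d["arm_names"] = tuple(d["arm_names"])
    if "n_per_arm" in d:
        d["n_per_arm"] = tuple(d["n_per_arm"])
    return TrialScenario(**d).validate()


def read_config(path) -> RunConfig:
    """Parse a YAML run configuration into a validated :class:`RunConfig`."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: configuration must be a mapping")
    kwargs = {}
    for key in ("country", "population", "seed", "comparator", "lenvatinib_share",
                "n_psa_draws", "outdir", "log_level"):
        if key in raw:
            kwargs[key] = raw[key]
    if "analyses" in raw:
        kwargs["analyses"] = tuple(raw["analyses"])
    if "psm" in raw:
        kwargs["psm"] = PSMConfig(**raw["psm"]).validate()
    if "scenario" in raw and raw["scenario"] is not None:
        kwargs["scenario"] = scenario_from_dict(raw["scenario"])
    if "econ" in raw and raw["econ"] is not None:
        kwargs["econ"] = econ_from_dict(raw["econ"])
    return RunConfig(**kwargs).validate()


def config_to_dict(config: RunConfig) -> dict:
    d = {
        "country": config.country,
        "population": config.population,
        "seed": config.seed,
        "comparator": config.comparator,
        "lenvatinib_share": config.lenvatinib_share,
        "analyses": list(config.analyses),
        "n_psa_draws": config.n_psa_draws,
        # outdir deliberately omitted: where results land does not change them
        "psm": dataclasses.asdict(config.psm),
    }
    if config.scenario is not None:
        d["scenario"] = dataclasses.asdict(config.scenario)
    if config.econ is not None:
        d["econ"] = econ_to_dict(config.econ)
    return d


def config_hash(config: RunConfig) -> str:
    canonical = json.dumps(config_to_dict(config), sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()


# ---------------------------------------------------------------------------
# result bundles
# ---------------------------------------------------------------------------

def _currency(values) -> list:
    return [round_currency(float(v)) for v in np.atleast_1d(values)]


def base_case_table(result: PipelineResult) -> pd.DataFrame:
    """Two strategy rows plus the incremental comparison, mirroring the
    usual base-case results layout."""
    ce = result.base_case
    rows = []
    for strat, inc_cost, inc_eff, icer_val in (
        (result.treat, ce.delta_cost, ce.delta_effect,
         ce.icer if ce.icer is not None else ""),
        (result.control, "", "", ""),
    ):
        rows.append(
            {
                "strategy": strat.label,
                "cost_usd": round_currency(strat.cost),
                "incremental_cost_usd": round_currency(inc_cost) if inc_cost != "" else "",
                "life_years": round(strat.life_years, 4),
                "qalys": round(strat.qalys, 4),
                "incremental_qalys": round(inc_eff, 4) if inc_eff != "" else "",
                "icer_usd_per_qaly": round_currency(icer_val) if icer_val != "" else "",
            }
        )
    return pd.DataFrame(rows)


def write_results(result: PipelineResult, outdir) -> dict:
    """Write every produced table plus the manifest; returns file map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}

    base_case_table(result).to_csv(out / "base_case.csv", index=False)
    files["base_case"] = "base_case.csv"

    breakdown_rows = []
    for strat in (result.treat, result.control):
        for cat, value in strat.breakdown.categories.items():
            breakdown_rows.append(
                {"strategy": strat.label, "category": cat, "cost_usd": round_currency(value)}
            )
        breakdown_rows.append(
            {"strategy": strat.label, "category": "total",
             "cost_usd": round_currency(strat.breakdown.total)}
        )
    pd.DataFrame(breakdown_rows).to_csv(out / "cost_breakdown.csv", index=False)
    files["cost_breakdown"] = "cost_breakdown.csv"

    for arm, eps in result.survival.grids.items():
        for endpoint, grid in eps.items():
            name = f"survivor_{arm.replace('/', '_').replace('+', '_')}_{endpoint}.csv"
            pd.DataFrame(
                {"cycle": np.arange(len(grid)), "survival": grid}
            ).to_csv(out / name, index=False)
    fit_rows = []
    for arm, eps in result.survival.gof.items():
        for endpoint, report in eps.items():
            table = report["table"].copy()
            table.insert(0, "endpoint", endpoint)
            table.insert(0, "arm", arm)
            fit_rows.append(table)
    pd.concat(fit_rows, ignore_index=True).assign(
        params=lambda df: df["params"].map(json.dumps)
    ).to_csv(out / "fit_table.csv", index=False)
    files["fit_table"] = "fit_table.csv"

    if result.tornado is not None:
        result.tornado.to_csv(out / "tornado.csv", index=False)
        files["tornado"] = "tornado.csv"
    if result.twoway is not None:
        result.twoway.to_csv(out / "twoway.csv", index=False)
        files["twoway"] = "twoway.csv"
    if result.psa_draws is not None:
        result.psa_draws.to_csv(out / "psa_draws.csv", index=False)
        files["psa_draws"] = "psa_draws.csv"
    if result.ceac_table is not None:
        result.ceac_table.to_csv(out / "ceac.csv", index=False)
        files["ceac"] = "ceac.csv"
    if result.thresholds is not None:
        payload = [dataclasses.asdict(t) for t in result.thresholds]
        (out / "thresholds.json").write_text(json.dumps(payload, indent=2))
        files["thresholds"] = "thresholds.json"
    if result.scenario_table is not None:
        result.scenario_table.to_csv(out / "scenarios.csv", index=False)
        files["scenarios"] = "scenarios.csv"

    manifest = {
        "package": "psmcea",
        "version": __version__,
        "seed": result.config.seed,
        "config_sha256": config_hash(result.config),
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    files["manifest"] = "manifest.json"
    return files
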