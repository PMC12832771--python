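"""Deterministic, probabilistic, threshold and scenario analyses.

All routines drive an abstract ``model_fn(overrides) -> CEResult``,
where ``overrides`` maps dotted parameter paths (``price.nivolumab``,
``utility.pfs``, ``discount_rate``, ...) to replacement values.  The
pipeline module provides the concrete closure; keeping the interface
functional makes every analysis trivially testable against toy models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .outcomes import CEResult

ModelFn = Callable[[dict], CEResult]


@dataclass(frozen=True)
class ParamRange:
    """One-way sensitivity range for a single parameter."""

    path: str
    base: float
    low: float
    high: float
    source: str = "±20%"

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ConfigurationError(
                f"{self.path}: require low <= base <= high, got "
                f"({self.low}, {self.base}, {self.high})"
            )


def pct20(path: str, base: float) -> ParamRange:
    """±20% range around a base value (the default when no CI exists)."""
    lo, hi = sorted((0.8 * base, 1.2 * base))
    return ParamRange(path, base, lo, hi, source="±20%")


@dataclass(frozen=True)
class PSAParam:
    """Distributional assumption for one PSA parameter.

    ``kind`` selects the family: gamma for costs/prices, beta for
    utilities.  Mean equals the base value; the SD defaults to 20% of
    the mean (overridable per parameter).
    """

    path: str
    base: float
    kind: str  # "gamma" | "beta"
    sd: Optional[float] = None

    def resolved_sd(self, sd_frac: float) -> float:
        return self.sd if self.sd is not None else sd_frac * abs(self.base)


@dataclass
class PSASpec:
    params: list  # of PSAParam
    n_draws: int = 1000
    sd_frac: float = 0.2
    seed: int = 0

    def validate(self) -> "PSASpec":
        if self.n_draws < 1:
            raise ConfigurationError("n_draws must be >= 1")
        for p in self.params:
            if p.kind not in ("gamma", "beta"):
                raise ConfigurationError(f"{p.path}: unknown distribution kind {p.kind!r}")
        return self


def gamma_moments(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments (shape, scale) for a gamma distribution."""
    if mean <= 0 or sd <= 0:
        raise ConfigurationError("gamma moments need positive mean and sd")
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return shape, scale


def beta_moments(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments (alpha, beta) for a beta distribution."""
    if not 0.0 < mean < 1.0:
        raise ConfigurationError("beta mean must lie in (0, 1)")
    var = sd * sd
    if var >= mean * (1.0 - mean):
        raise ConfigurationError(
            f"beta moments infeasible: sd^2 = {var:g} >= m(1-m) = {mean * (1 - mean):g}"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def sample_parameter(param: PSAParam, sd_frac: float, rng: np.random.Generator,
                     size: int) -> np.ndarray:
    sd = param.resolved_sd(sd_frac)
    if sd == 0.0 or param.base == 0.0:
        return np.full(size, param.base)
    if param.kind == "gamma":
        shape, scale = gamma_moments(param.base, sd)
        return rng.gamma(shape, scale, size=size)
    alpha, beta = beta_moments(param.base, sd)
    return rng.beta(alpha, beta, size=size)


# ---------------------------------------------------------------------------
# one-way / two-way deterministic sensitivity
# ---------------------------------------------------------------------------

def one_way_sa(model_fn: ModelFn, ranges: Sequence[ParamRange]) -> pd.DataFrame:
    """Tornado table: each parameter moved alone to its low/high value.

    Rows are sorted by the absolute ICER spread, largest first; a model
    failure at an extreme flags the row instead of dropping it.
    """
    rows = []
    for pr in ranges:
        row = {"param": pr.path, "base": pr.base, "low": pr.low, "high": pr.high,
               "source": pr.source, "failed": False}
        try:
            res_low = model_fn({pr.path: pr.low})
            res_high = model_fn({pr.path: pr.high})
            row["icer_low"] = res_low.icer if res_low.icer is not None else math.nan
            row["icer_high"] = res_high.icer if res_high.icer is not None else math.nan
            row["spread"] = abs(row["icer_high"] - row["icer_low"])
        except Exception as exc:  # model failure at an extreme
            row.update(icer_low=math.nan, icer_high=math.nan, spread=math.nan,
                       failed=True, error=str(exc))
        rows.append(row)
    table = pd.DataFrame(rows)
    return table.sort_values("spread", ascending=False, na_position="last").reset_index(
        drop=True
    )


def two_way_sa(model_fn: ModelFn, range_a: ParamRange, range_b: ParamRange,
               grid_size: int = 11, wtp: Optional[float] = None) -> pd.DataFrame:
    """Full-factorial grid over two parameters (typically the two drug
    prices); records the ICER and cost-effectiveness of every cell."""
    if grid_size < 2:
        raise ConfigurationError("grid_size must be >= 2")
    a_values = np.linspace(range_a.low, range_a.high, grid_size)
    b_values = np.linspace(range_b.low, range_b.high, grid_size)
    rows = []
    for a in a_values:
        for b in b_values:
            res = model_fn({range_a.path: float(a), range_b.path: float(b)})
            threshold = wtp if wtp is not None else res.wtp
            ce = res.status == "dominant" or (
                res.icer is not None and res.delta_effect > 0 and res.icer < threshold
            )
            rows.append(
                {range_a.path: float(a), range_b.path: float(b),
                 "icer": res.icer if res.icer is not None else math.nan,
                 "status": res.status, "cost_effective": bool(ce)}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

def psa(model_fn: ModelFn, spec: PSASpec) -> pd.DataFrame:
    """Monte Carlo draws of (delta cost, delta QALY) with all listed
    parameters varied simultaneously; reproducible for a fixed seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    samples = {
        p.path: sample_parameter(p, spec.sd_frac, rng, spec.n_draws) for p in spec.params
    }
    rows = []
    for i in range(spec.n_draws):
        overrides = {path: float(vals[i]) for path, vals in samples.items()}
        res = model_fn(overrides)
        rows.append(
            {"draw": i, "dcost": res.delta_cost, "dqaly": res.delta_effect,
             "icer": res.icer if res.icer is not None else math.nan}
        )
    return pd.DataFrame(rows)


def ceac(draws: pd.DataFrame, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve: at each WTP, the exact
    fraction of draws with positive net monetary benefit."""
    if len(draws) == 0:
        raise ConfigurationError("ceac requires >= 1 draw")
    dc = draws["dcost"].to_numpy()
    de = draws["dqaly"].to_numpy()
    rows = []
    for w in wtp_grid:
        if w < 0:
            raise ConfigurationError("WTP must be >= 0")
        prob = float(np.mean(w * de - dc > 0.0))
        rows.append({"wtp": float(w), "probability": prob})
    return pd.DataFrame(rows)


#: printed WTP grids used as defaults (USD per QALY)
WTP_GRID_US = (50_000.0, 100_000.0, 150_000.0)
WTP_GRID_CHINA = (22_031.53, 39_933.67, 95_160.78)


# ---------------------------------------------------------------------------
# price-threshold search
# ---------------------------------------------------------------------------

@dataclass
class ThresholdResult:
    drug: str
    wtp: float
    multiplier: Optional[float]
    achieved_icer: Optional[float]
    status: str  # "solved" | "always" | "never"


def price_threshold(model_fn: ModelFn, drug_paths: Sequence[str], wtp: float,
                    bounds: tuple[float, float] = (0.01, 3.0),
                    base_prices: Optional[dict] = None,
                    rel_tol: float = 1e-4, max_iter: int = 200) -> ThresholdResult:
    """Bisection for the price multiplier m* at which ICER(m*) = WTP.

    ``drug_paths`` lists the override paths whose base values are scaled
    jointly by the multiplier (one path for a single-drug threshold, two
    for a simultaneous reduction).  ``base_prices`` maps each path to
    its base value; ICER monotonicity over the bracket is verified
    numerically.  When the ICER never crosses the WTP inside the bounds
    the result reports "always" or "never" cost-effective instead of a
    multiplier.
    """
    if base_prices is None:
        raise ConfigurationError("base_prices mapping is required")
    if not 0 < bounds[0] < bounds[1]:
        raise ConfigurationError("bounds must satisfy 0 < low < high")

    def icer_at(m: float) -> float:
        overrides = {p: m * base_prices[p] for p in drug_paths}
        res = model_fn(overrides)
        if res.icer is None:
            # dominant => effectively -inf, dominated with dE<=0 => +inf
            return -math.inf if res.status == "dominant" else math.inf
        return res.icer

    lo, hi = bounds
    f_lo = icer_at(lo) - wtp
    f_hi = icer_at(hi) - wtp
    f_mid = icer_at(0.5 * (lo + hi)) - wtp
    finite = [v for v in (f_lo, f_mid, f_hi) if math.isfinite(v)]
    ascending = all(x <= y + 1e-9 for x, y in zip(finite, finite[1:]))
    descending = all(x >= y - 1e-9 for x, y in zip(finite, finite[1:]))
    if len(finite) >= 2 and not (ascending or descending):
        raise ConfigurationError("ICER is not monotone in the price multiplier")
    if f_lo * f_hi > 0:
        status = "always" if f_hi < 0 else "never"
        return ThresholdResult("+".join(drug_paths), wtp, None, None, status)

    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = icer_at(mid) - wtp
        if abs(f_mid) / wtp < rel_tol:
            return ThresholdResult("+".join(drug_paths), wtp, mid, f_mid + wtp, "solved")
        if (f_mid > 0) == (f_hi > 0):
            hi, f_hi = mid, f_mid
        else:
            lo, f_lo = mid, f_mid
    mid = 0.5 * (lo + hi)
    return ThresholdResult("+".join(drug_paths), wtp, mid, icer_at(mid), "solved")


# ---------------------------------------------------------------------------
# scenario runner
# ---------------------------------------------------------------------------

SCENARIO_KEYS = {
    "pfs_source", "exclude_ae_disutility", "horizon_years", "pfs_only_accrual",
    "comparator", "population",
}


def validate_scenario(scenario: dict) -> dict:
    unknown = set(scenario) - SCENARIO_KEYS
    if unknown:
        raise ConfigurationError(f"unknown scenario keys: {sorted(unknown)}")
    horizon = scenario.get("horizon_years")
    if horizon is not None and horizon not in (4, 5, 10, 20):
        raise ConfigurationError("horizon_years must be one of 4, 5, 10, 20")
    comparator = scenario.get("comparator")
    if comparator is not None and comparator not in ("blend", "lenvatinib", "sorafenib"):
        raise ConfigurationError(f"unknown comparator {comparator!r}")
    population = scenario.get("population")
    if population is not None and population not in ("ITT", "China-subgroup"):
        raise ConfigurationError(f"unknown population {population!r}")
    return scenario
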