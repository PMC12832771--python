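"""Parametric survival families shared by the simulator and the fitting stage.

Five families are supported, parameterised as

* ``exponential``  S(t) = exp(-rate * t)
* ``weibull``      S(t) = exp(-(t / scale)**shape)
* ``gompertz``     S(t) = exp(-(rate / shape) * (exp(shape * t) - 1))
* ``lognormal``    S(t) = 1 - Phi((ln t - mu) / sigma)
* ``loglogistic``  S(t) = 1 / (1 + (t / scale)**shape)

Time is in months throughout.  The Gompertz ``shape`` may be negative
(decreasing hazard, improper survivor with plateau exp(rate/shape)); all
other shape/scale/rate parameters must be strictly positive.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import special

from .errors import ConfigurationError

FAMILIES = ("exponential", "weibull", "gompertz", "lognormal", "loglogistic")

#: number of free parameters per family
N_PARAMS = {
    "exponential": 1,
    "weibull": 2,
    "gompertz": 2,
    "lognormal": 2,
    "loglogistic": 2,
}

PARAM_NAMES = {
    "exponential": ("rate",),
    "weibull": ("shape", "scale"),
    "gompertz": ("shape", "rate"),
    "lognormal": ("mu", "sigma"),
    "loglogistic": ("shape", "scale"),
}


def _check_family(family: str) -> None:
    if family not in FAMILIES:
        raise ConfigurationError(
            f"unknown survival family {family!r}; expected one of {FAMILIES}"
        )


def validate_params(family: str, params: dict) -> None:
    """Raise :class:`ConfigurationError` if ``params`` are outside the domain."""
    _check_family(family)
    names = PARAM_NAMES[family]
    missing = set(names) - set(params)
    if missing:
        raise ConfigurationError(f"{family}: missing parameters {sorted(missing)}")
    for name in names:
        value = float(params[name])
        if not math.isfinite(value):
            raise ConfigurationError(f"{family}: parameter {name} is not finite")
        # mu (lognormal) and shape (gompertz) are free reals; everything else > 0
        if name == "mu" or (family == "gompertz" and name == "shape"):
            continue
        if value <= 0.0:
            raise ConfigurationError(
                f"{family}: parameter {name} must be positive, got {value}"
            )


def survival(family: str, params: dict, t) -> np.ndarray | float:
    """Survivor function S(t) for one family; S(0) = 1, non-increasing."""
    validate_params(family, params)
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ConfigurationError("survival requires t >= 0")
    if family == "exponential":
        out = np.exp(-params["rate"] * t_arr)
    elif family == "weibull":
        out = np.exp(-((t_arr / params["scale"]) ** params["shape"]))
    elif family == "gompertz":
        a, b = params["shape"], params["rate"]
        if abs(a) < 1e-12:
            out = np.exp(-b * t_arr)
        else:
            out = np.exp(-(b / a) * np.expm1(a * t_arr))
    elif family == "lognormal":
        mu, sigma = params["mu"], params["sigma"]
        with np.errstate(divide="ignore"):
            z = (np.log(np.maximum(t_arr, 1e-300)) - mu) / sigma
        out = special.ndtr(-z)
        out = np.where(t_arr <= 0.0, 1.0, out)
    else:  # loglogistic
        beta, alpha = params["shape"], params["scale"]
        out = 1.0 / (1.0 + (t_arr / alpha) ** beta)
    if np.ndim(t) == 0:
        return float(out)
    return out


def log_density(family: str, params: dict, t) -> np.ndarray:
    """Log event density ln f(t) on t > 0 (censored likelihood contributions
    use ``log_survival`` instead)."""
    validate_params(family, params)
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr <= 0):
        raise ConfigurationError("log_density requires t > 0")
    lt = np.log(t_arr)
    if family == "exponential":
        lam = params["rate"]
        return math.log(lam) - lam * t_arr
    if family == "weibull":
        k, s = params["shape"], params["scale"]
        return (
            math.log(k) - math.log(s) + (k - 1.0) * (lt - math.log(s))
            - (t_arr / s) ** k
        )
    if family == "gompertz":
        a, b = params["shape"], params["rate"]
        if abs(a) < 1e-12:
            return math.log(b) - b * t_arr
        return math.log(b) + a * t_arr - (b / a) * np.expm1(a * t_arr)
    if family == "lognormal":
        mu, sigma = params["mu"], params["sigma"]
        z = (lt - mu) / sigma
        return -lt - math.log(sigma) - 0.5 * math.log(2.0 * math.pi) - 0.5 * z * z
    # loglogistic
    beta, alpha = params["shape"], params["scale"]
    la = math.log(alpha)
    return (
        math.log(beta) - la + (beta - 1.0) * (lt - la)
        - 2.0 * np.log1p((t_arr / alpha) ** beta)
    )


def log_survival(family: str, params: dict, t) -> np.ndarray:
    """Log survivor function, numerically stable in the far tail."""
    validate_params(family, params)
    t_arr = np.asarray(t, dtype=float)
    if family == "exponential":
        return -params["rate"] * t_arr
    if family == "weibull":
        return -((t_arr / params["scale"]) ** params["shape"])
    if family == "gompertz":
        a, b = params["shape"], params["rate"]
        if abs(a) < 1e-12:
            return -b * t_arr
        return -(b / a) * np.expm1(a * t_arr)
    if family == "lognormal":
        mu, sigma = params["mu"], params["sigma"]
        with np.errstate(divide="ignore"):
            z = (np.log(np.maximum(t_arr, 1e-300)) - mu) / sigma
        out = special.log_ndtr(-z)
        return np.where(t_arr <= 0.0, 0.0, out)
    beta, alpha = params["shape"], params["scale"]
    return -np.log1p((t_arr / alpha) ** beta)


def survival_quantile(family: str, params: dict, u) -> np.ndarray | float:
    """Inverse survivor: the time t at which S(t) = u, for u in (0, 1].

    Returns ``inf`` where the survivor plateaus above ``u`` (possible for
    Gompertz with negative shape).
    """
    validate_params(family, params)
    u_arr = np.asarray(u, dtype=float)
    if np.any((u_arr <= 0.0) | (u_arr > 1.0)):
        raise ConfigurationError("survival_quantile requires u in (0, 1]")
    log_u = np.log(u_arr)
    if family == "exponential":
        out = -log_u / params["rate"]
    elif family == "weibull":
        k, s = params["shape"], params["scale"]
        out = s * (-log_u) ** (1.0 / k)
    elif family == "gompertz":
        a, b = params["shape"], params["rate"]
        if abs(a) < 1e-12:
            out = -log_u / b
        else:
            arg = 1.0 - (a / b) * log_u
            with np.errstate(invalid="ignore", divide="ignore"):
                out = np.where(arg > 0.0, np.log(np.maximum(arg, 1e-300)) / a, np.inf)
    elif family == "lognormal":
        mu, sigma = params["mu"], params["sigma"]
        out = np.exp(mu + sigma * special.ndtri(1.0 - u_arr))
    else:  # loglogistic
        beta, alpha = params["shape"], params["scale"]
        out = alpha * ((1.0 - u_arr) / u_arr) ** (1.0 / beta)
    if np.ndim(u) == 0:
        return float(out)
    return out


def exponential_rate_from_median(median: float) -> float:
    """Rate of an exponential with the given median survival time."""
    if median <= 0:
        raise ConfigurationError("median must be positive")
    return math.log(2.0) / median


def weibull_scale_from_median(median: float, shape: float) -> float:
    """Weibull scale such that S(median) = 1/2 at the given shape."""
    if median <= 0 or shape <= 0:
        raise ConfigurationError("median and shape must be positive")
    return median / math.log(2.0) ** (1.0 / shape)
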