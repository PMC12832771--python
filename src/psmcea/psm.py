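"""Partitioned survival model: survivor curves to health-state occupancy.

Four states — progression-free on first-line therapy (PFS), the
second-line phase between first and second progression (PFS2),
progressive disease after second progression (PD), and death — with
monthly cycles.  Occupancy is read directly off the overall-survival and
progression-free survivor curves:

    PFS(t)   = min(S_pfs(t), S_os(t))
    Death(t) = 1 - S_os(t)
    PFS2(t) + PD(t) = S_os(t) - PFS(t)

The split of the post-progression remainder between PFS2 and PD is not
identified by the two curves; it is modelled by giving each progressing
cohort an exponential time in PFS2 with configurable monthly exit hazard
``pfs2_exit_rate`` (per-cycle exit probability 1 - exp(-rate)), truncated
so PFS2 never exceeds the remainder.  Setting the rate to 0 keeps all
post-progression mass in PFS2; a very large rate empties PFS2 into PD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

#: default monthly hazard of leaving PFS2 (median 6 months in second line)
DEFAULT_PFS2_EXIT_RATE = math.log(2.0) / 6.0


@dataclass
class PSMConfig:
    """Cycle structure and the PFS2-duration assumption."""

    n_cycles: int = 240
    pfs2_exit_rate: float = DEFAULT_PFS2_EXIT_RATE
    half_cycle_correction: bool = False
    cycle_length_months: float = 1.0  # fixed by the model design

    def validate(self) -> "PSMConfig":
        if self.n_cycles < 1:
            raise ConfigurationError("n_cycles must be >= 1")
        if self.pfs2_exit_rate < 0:
            raise ConfigurationError("pfs2_exit_rate must be >= 0")
        if self.cycle_length_months != 1.0:
            raise ConfigurationError("cycle length is fixed at one month")
        return self


@dataclass
class StateTrace:
    """Per-cycle occupancy (cycle boundaries 0..n_cycles) of the four states."""

    pfs: np.ndarray
    pfs2: np.ndarray
    pd: np.ndarray
    death: np.ndarray
    incident_deaths: np.ndarray       # deaths occurring in cycle t (index 0 unused)
    incident_progressions: np.ndarray
    half_cycle_correction: bool = False
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_cycles(self) -> int:
        return len(self.pfs) - 1

    def occupancy(self, state: str) -> np.ndarray:
        return {"pfs": self.pfs, "pfs2": self.pfs2, "pd": self.pd,
                "death": self.death}[state]

    def alive(self) -> np.ndarray:
        return self.pfs + self.pfs2 + self.pd

    def validate(self, atol: float = 1e-9) -> "StateTrace":
        total = self.pfs + self.pfs2 + self.pd + self.death
        if np.any(np.abs(total - 1.0) > atol):
            raise DataError("state occupancies do not sum to 1")
        for arr in (self.pfs, self.pfs2, self.pd, self.death):
            if np.any(arr < -atol):
                raise DataError("negative occupancy")
        if np.any(np.diff(self.death) < -atol):
            raise DataError("death occupancy must be non-decreasing")
        if np.any(np.diff(self.pfs) > atol):
            raise DataError("PFS occupancy must be non-increasing")
        return self

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": np.arange(self.n_cycles + 1),
                "pfs": self.pfs,
                "pfs2": self.pfs2,
                "pd": self.pd,
                "death": self.death,
                "incident_deaths": self.incident_deaths,
                "incident_progressions": self.incident_progressions,
            }
        )


def compute_occupancy(s_pfs: np.ndarray, s_os: np.ndarray, config: PSMConfig) -> StateTrace:
    """Partition the two survivor grids into four-state occupancy.

    ``s_pfs`` and ``s_os`` are survivor probabilities at cycle boundaries
    0..n_cycles (so length >= n_cycles + 1) with S(0) = 1.  Crossings
    where the extrapolated PFS exceeds OS are repaired with the standard
    min() cap and counted in the diagnostics.
    """
    config = config.validate()
    n = config.n_cycles
    s_pfs = np.asarray(s_pfs, dtype=float)
    s_os = np.asarray(s_os, dtype=float)
    if len(s_pfs) < n + 1 or len(s_os) < n + 1:
        raise DataError(
            f"survivor grids must cover cycles 0..{n}; got lengths "
            f"{len(s_pfs)} and {len(s_os)}"
        )
    s_pfs = s_pfs[: n + 1]
    s_os = s_os[: n + 1]
    if abs(s_pfs[0] - 1.0) > 1e-9 or abs(s_os[0] - 1.0) > 1e-9:
        raise DataError("survivor grids must start at S(0) = 1")

    n_capped = int(np.sum(s_pfs > s_os + 1e-15))
    pfs = np.minimum(s_pfs, s_os)
    death = 1.0 - s_os
    remainder = s_os - pfs  # post-progression, pre-death mass

    # cohort convolution: mass entering the remainder at cycle s stays in
    # PFS2 with per-cycle retention exp(-rate), counted from the end of the
    # entry cycle so that an infinite rate empties PFS2 immediately
    stay = math.exp(-config.pfs2_exit_rate)
    entrants = np.maximum(np.diff(remainder, prepend=0.0), 0.0)
    pfs2_raw = np.zeros(n + 1)
    for t in range(1, n + 1):
        pfs2_raw[t] = stay * (pfs2_raw[t - 1] + entrants[t])
    pfs2 = np.minimum(pfs2_raw, remainder)
    pd_state = remainder - pfs2

    incident_deaths = np.maximum(np.diff(death, prepend=0.0), 0.0)
    incident_deaths[0] = 0.0
    incident_prog = entrants.copy()
    incident_prog[0] = 0.0

    trace = StateTrace(
        pfs=pfs,
        pfs2=pfs2,
        pd=pd_state,
        death=death,
        incident_deaths=incident_deaths,
        incident_progressions=incident_prog,
        half_cycle_correction=config.half_cycle_correction,
        diagnostics={"n_cycles_pfs_capped": n_capped},
    )
    return trace.validate()


def cycle_discount_factors(rate: float, n_cycles: int) -> np.ndarray:
    """(1 + r)^(-t/12) for t = 0..n_cycles (annual rate, monthly cycles)."""
    if rate < 0:
        raise ConfigurationError("discount rate must be >= 0")
    t = np.arange(n_cycles + 1, dtype=float)
    return (1.0 + rate) ** (-t / 12.0)


def _accrual_weights(values: np.ndarray, half_cycle: bool) -> np.ndarray:
    """Per-cycle accrued occupancy for cycles 1..n: end-of-cycle value by
    default, trapezoid of adjacent boundaries under half-cycle correction."""
    if half_cycle:
        return 0.5 * (values[:-1] + values[1:])
    return values[1:]


def life_years(trace: StateTrace, discount_rate: float,
               alive_states=("pfs", "pfs2", "pd")) -> float:
    """Discounted life-years accrued in the given states over the horizon."""
    if discount_rate < 0:
        raise ConfigurationError("discount rate must be >= 0")
    occ = np.zeros(trace.n_cycles + 1)
    for state in alive_states:
        occ = occ + trace.occupancy(state)
    df = cycle_discount_factors(discount_rate, trace.n_cycles)[1:]
    accrued = _accrual_weights(occ, trace.half_cycle_correction)
    return float(np.sum(accrued * df) / 12.0)
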