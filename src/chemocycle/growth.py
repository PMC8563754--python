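"""Gompertz tumor growth, cell-count bookkeeping, and regimen schedules.

Cell numbers follow the Gompertz law

    n(t) = N * exp{ ln(N_inf / N) * [1 - exp(-b t)] }

with carrying capacity N_inf and growth rate b (1/month).  Healthy tissue
regrows with the same law at half the rate and with its own baseline N_1 as
carrying capacity.  Schedules are ordered injection events (time in months,
dose as a fraction of the reference plasma peak C_p); the three named
regimen builders follow the usual clinical archetypes:

* MTD — full dose every 0.5 month;
* LDC (metronomic) — 0.2 dose every 0.1 month;
* CS (chemo-switching) — repeating block of one full dose, a 0.5-month
  break, then five 0.2 doses at 0.1-month intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "MONTH_S",
    "GrowthParams",
    "Schedule",
    "gompertz_growth",
    "apply_kill",
    "build_regimen",
    "replay_reported_cycle_chain",
]

#: One month in seconds (30.4375 days).
MONTH_S = 30.4375 * 86400.0


@dataclass
class GrowthParams:
    """Gompertz parameters and tumor/healthy bookkeeping constants.

    Defaults are the standard literature values for a ~5e9-cell tumor:
    N_0 = 5e9, N_inf = 3.1e12, b = 0.0283 /month; healthy baseline
    N_1 = 4.64e12 cells with half the tumor growth rate and a
    healthy-to-tumor density ratio of 0.2.
    """

    n0: float = 5e9
    n_inf: float = 3.1e12
    b: float = 0.0283              # 1/month
    n1: float = 4.64e12
    healthy_rate_factor: float = 0.5
    density_ratio: float = 0.2

    def __post_init__(self):
        if not (0 < self.n0 < self.n_inf):
            raise ValueError("need 0 < N_0 < N_inf")
        if self.b <= 0:
            raise ValueError("growth rate b must be positive")


@dataclass
class Schedule:
    """Ordered injection events: (time in months, dose fraction of C_p)."""

    events: list[tuple[float, float]]
    horizon_months: float

    def __post_init__(self):
        times = [t for t, _ in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        if any(d <= 0 for _, d in self.events):
            raise ValueError("dose fractions must be positive")
        if self.horizon_months <= 0:
            raise ValueError("schedule horizon must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.events])

    @property
    def doses(self) -> np.ndarray:
        return np.array([d for _, d in self.events])

    def total_dose(self) -> float:
        return float(sum(d for _, d in self.events))


def gompertz_growth(n_i: float, t_months: float, gp: GrowthParams,
                    rate_factor: float = 1.0, carrying: Optional[float] = None) -> float:
    """Gompertz cell count after ``t_months`` starting from ``n_i`` cells.

    ``rate_factor`` scales b (0.5 for healthy tissue); ``carrying``
    overrides N_inf (healthy tissue saturates at its own baseline).
    """
    n_sat = gp.n_inf if carrying is None else carrying
    if n_i <= 0:
        raise ValueError("cell count must be positive")
    if n_i > n_sat * (1 + 1e-12):
        raise ValueError("Gompertz model undefined above the carrying capacity")
    if t_months < 0:
        raise ValueError("time must be non-negative")
    n_i = min(n_i, n_sat)
    return float(n_i * np.exp(np.log(n_sat / n_i) * (1.0 - np.exp(-gp.b * rate_factor * t_months))))


def apply_kill(n: float, fkc: float) -> float:
    """Surviving cells after a treatment killing the fraction ``fkc``."""
    if not (0.0 <= fkc <= 1.0):
        raise ValueError("killed fraction must lie in [0, 1]")
    return n * (1.0 - fkc)


_EPS = 1e-9  # inclusive-endpoint slack when cutting schedules, months


def build_regimen(kind: str, horizon_months: float,
                  mtd_dose: float = 1.0, mtd_interval: float = 0.5,
                  ldc_dose: float = 0.2, ldc_interval: float = 0.1,
                  custom_events: Optional[Sequence[tuple[float, float]]] = None) -> Schedule:
    """Build a named regimen schedule up to (and including) the horizon.

    kind: 'MTD', 'LDC' (metronomic), 'CS' (chemo-switching) or 'custom'.
    Events landing exactly on the horizon are included.
    """
    kind = kind.upper()
    if horizon_months <= 0:
        raise ValueError("horizon must be positive")
    events: list[tuple[float, float]] = []
    if kind == "MTD":
        t = 0.0
        while t <= horizon_months + _EPS:
            events.append((t, mtd_dose))
            t += mtd_interval
    elif kind in ("LDC", "MC"):
        t = 0.0
        while t <= horizon_months + _EPS:
            events.append((round(t, 12), ldc_dose))
            t += ldc_interval
    elif kind == "CS":
        block = 0.0
        while block <= horizon_months + _EPS:
            events.append((block, mtd_dose))
            for k in range(5):
                t = block + mtd_interval + k * ldc_interval
                if t <= horizon_months + _EPS:
                    events.append((round(t, 12), ldc_dose))
            block += mtd_interval + 5 * ldc_interval
    elif kind == "CUSTOM":
        if not custom_events:
            raise ValueError("custom regimen needs an explicit event list")
        events = [(float(t), float(d)) for t, d in custom_events if t <= horizon_months + _EPS]
    else:
        raise ValueError(f"unknown regimen kind: {kind!r}")
    return Schedule(events=events, horizon_months=horizon_months)


def replay_reported_cycle_chain(kill_pcts: Sequence[float],
                                regrowth_pcts: Sequence[float]) -> float:
    """Replay a per-cycle percentage chain of kills and regrowths.

    Starting from 100% of the initial tumor cells, alternately subtract the
    killed percentage points and add the regrowth percentage points; the
    bookkeeping treats both as additive changes relative to the initial cell
    count.  Returns the remaining percentage.
    """
    if len(regrowth_pcts) != len(kill_pcts) - 1:
        raise ValueError("need exactly one fewer regrowth entry than kill entries")
    value = 100.0
    for i, kill in enumerate(kill_pcts):
        value -= kill
        if value < 0:
            raise ValueError(f"cycle chain went negative after kill {i + 1}")
        if i < len(regrowth_pcts):
            value += regrowth_pcts[i]
    return value
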