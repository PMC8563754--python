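"""Sequential treatment cycles: delivery -> kill -> regrowth -> shrink.

Each injection event of a schedule runs one full cycle: (i) the coupled
microvascular/interstitial flow is solved on the current geometry; (ii) the
delivery phase transports the drug and accumulates internalized
concentration; (iii) tumor and normal-tissue killed fractions are computed
and the cell counts updated; (iv) both populations regrow by the Gompertz
law over the drug-free remainder of the break (tumor at full rate b,
healthy tissue at b/2 with its baseline as carrying capacity); (v) the
tumor radius is rescaled by the cube-root of the cell-count ratio.  The
capillary network structure is held fixed across cycles; segments left
outside the shrinking tumor adopt normal-tissue wall parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .coupling import smooth_sources, solve_coupled_flow
from .growth import MONTH_S, GrowthParams, Schedule, apply_kill, gompertz_growth
from .pharmacodynamics import fraction_killed, side_effects
from .tissue import TissueGrid, build_domain, map_vessel_sources
from .transport import DrugParams, simulate_delivery_phase
from .vasculature import VascularNetwork

__all__ = ["CycleRecord", "TreatmentHistory", "run_protocol"]


@dataclass
class CycleRecord:
    """Bookkeeping of one treatment cycle."""

    cycle: int
    t_month: float
    dose: float
    tumor_radius_m: float
    n_before: float
    fkc_tumor: float
    n_after_kill: float
    regrow_months: float
    n_after_regrow: float
    fkc_normal: float
    healthy_before: float
    healthy_after_kill: float
    healthy_after_regrow: float
    kill_pp: float          # killed cells, percentage points of N_0
    regrowth_pp: float      # regrown cells, percentage points of N_0
    survival_pct: float     # 100 * N / N_0 at end of cycle
    side_effect_pct: float  # 100 * (1 - H / N_1) at end of cycle

    @property
    def s_f(self) -> float:
        """Surviving fraction of this cycle's kill, N_i / N_{i-1}."""
        return self.n_after_kill / self.n_before

    @property
    def growth_factor(self) -> float:
        return self.n_after_regrow / self.n_after_kill


@dataclass
class TreatmentHistory:
    """Per-cycle records of one simulated protocol."""

    cycles: list[CycleRecord]
    growth: GrowthParams
    schedule: Schedule

    @property
    def n_final(self) -> float:
        return self.cycles[-1].n_after_regrow if self.cycles else self.growth.n0

    @property
    def survival_pct(self) -> float:
        """Final tumor survival, % of the initial cell count."""
        return 100.0 * self.n_final / self.growth.n0

    @property
    def side_effect_pct(self) -> float:
        """Final cumulative side effect, % of the healthy baseline killed."""
        if not self.cycles:
            return 0.0
        return 100.0 * (1.0 - self.cycles[-1].healthy_after_regrow / self.growth.n1)

    def kill_pps(self) -> list[float]:
        return [c.kill_pp for c in self.cycles]

    def regrowth_pps(self) -> list[float]:
        return [c.regrowth_pp for c in self.cycles[:-1]]

    def survival_product(self) -> float:
        """Product of per-cycle surviving fractions and growth factors."""
        out = 1.0
        for c in self.cycles:
            out *= c.s_f * c.growth_factor
        return out

    def to_frame(self) -> pd.DataFrame:
        cols = [f.name for f in CycleRecord.__dataclass_fields__.values()]  # type: ignore[attr-defined]
        df = pd.DataFrame([{k: getattr(c, k) for k in cols} for c in self.cycles])
        df["s_f"] = [c.s_f for c in self.cycles]
        df["growth_factor"] = [c.growth_factor for c in self.cycles]
        return df

    def summary(self) -> dict:
        return {
            "n_cycles": len(self.cycles),
            "survival_pct": self.survival_pct,
            "side_effect_pct": self.side_effect_pct,
            "final_cells": self.n_final,
            "total_dose": self.schedule.total_dose(),
            "kill_pp": self.kill_pps(),
            "regrowth_pp": self.regrowth_pps(),
        }


def run_protocol(
    network: VascularNetwork,
    grid: TissueGrid,
    drug: DrugParams,
    schedule: Schedule,
    gp: GrowthParams,
    delivery_hours: float = 24.0,
    rtol: float = 1e-5,
    mu_plasma: float = 1e-3,
    rescale_geometry: bool = True,
    fkc_override: Optional[Callable[[int], tuple[float, float]]] = None,
    snapshot_hook: Optional[Callable] = None,
) -> TreatmentHistory:
    """Run a full treatment schedule and return its history.

    Parameters
    ----------
    network, grid :
        Vasculature and initial tissue geometry (the grid's tumor radius is
        the pre-treatment radius).
    drug, schedule, gp :
        Drug constants, injection schedule, and growth parameters.
    delivery_hours :
        Duration of each delivery phase (capped by the following break).
    rescale_geometry :
        If false the tumor mask is frozen across cycles (diagnostic mode).
    fkc_override :
        Optional ``cycle_index -> (fkc_tumor, fkc_normal)`` replacing the
        spatial kill computation (used for closed-form bookkeeping checks;
        the flow/transport solves are skipped).
    snapshot_hook :
        Optional callback ``(cycle_index, grid, flow, delivery)`` invoked
        after each delivery phase, e.g. to write field snapshots.
    """
    if not schedule.events:
        # no-treatment limit: pure Gompertz growth over the horizon
        n_end = gompertz_growth(gp.n0, schedule.horizon_months, gp)
        rec = CycleRecord(
            cycle=0, t_month=0.0, dose=0.0, tumor_radius_m=grid.tumor_radius,
            n_before=gp.n0, fkc_tumor=0.0, n_after_kill=gp.n0,
            regrow_months=schedule.horizon_months, n_after_regrow=n_end,
            fkc_normal=0.0, healthy_before=gp.n1, healthy_after_kill=gp.n1,
            healthy_after_regrow=gp.n1,
            kill_pp=0.0, regrowth_pp=100.0 * (n_end - gp.n0) / gp.n0,
            survival_pct=100.0 * n_end / gp.n0, side_effect_pct=0.0,
        )
        return TreatmentHistory(cycles=[rec], growth=gp, schedule=schedule)

    n = gp.n0
    healthy = gp.n1
    records: list[CycleRecord] = []
    times = list(schedule.times) + [schedule.horizon_months]
    base_radius = grid.tumor_radius
    sv_map = None
    if fkc_override is None:
        sv_map = smooth_sources(map_vessel_sources(network, grid), grid.h)
        grid.sv = sv_map

    for i, (t_ev, dose) in enumerate(schedule.events):
        break_months = max(times[i + 1] - t_ev, 0.0)
        delivery_s = min(delivery_hours * 3600.0, break_months * MONTH_S)
        if delivery_s <= 0:
            delivery_s = delivery_hours * 3600.0

        if fkc_override is not None:
            fkc_t, fkc_n = fkc_override(i)
        else:
            flow = solve_coupled_flow(network, grid, mu_plasma=mu_plasma, map_sources=False)
            delivery = simulate_delivery_phase(
                grid, flow, drug, [(0.0, dose)], horizon=delivery_s, rtol=rtol,
            )
            c_int_end = delivery.c_int[-1]
            fkc_t = fraction_killed(c_int_end, drug.omega, grid.tumor_mask)
            fkc_n = side_effects(c_int_end, drug.omega, grid.normal_mask())
            if snapshot_hook is not None:
                snapshot_hook(i, grid, flow, delivery)

        try:
            n_killed = apply_kill(n, fkc_t)
        except ValueError as exc:
            raise RuntimeError(f"cycle {i}: {exc}") from exc
        healthy_killed = apply_kill(healthy, fkc_n)

        regrow_months = max(break_months - delivery_s / MONTH_S, 0.0)
        n_regrown = gompertz_growth(n_killed, regrow_months, gp)
        healthy_regrown = gompertz_growth(
            healthy_killed, regrow_months, gp,
            rate_factor=gp.healthy_rate_factor, carrying=gp.n1,
        )

        records.append(CycleRecord(
            cycle=i, t_month=t_ev, dose=dose, tumor_radius_m=grid.tumor_radius,
            n_before=n, fkc_tumor=fkc_t, n_after_kill=n_killed,
            regrow_months=regrow_months, n_after_regrow=n_regrown,
            fkc_normal=fkc_n, healthy_before=healthy,
            healthy_after_kill=healthy_killed, healthy_after_regrow=healthy_regrown,
            kill_pp=100.0 * (n - n_killed) / gp.n0,
            regrowth_pp=100.0 * (n_regrown - n_killed) / gp.n0,
            survival_pct=100.0 * n_regrown / gp.n0,
            side_effect_pct=100.0 * (1.0 - healthy_regrown / gp.n1),
        ))
        n, healthy = n_regrown, healthy_regrown

        if rescale_geometry:
            r_new = base_radius * (n / gp.n0) ** (1.0 / 3.0)
            grid = build_domain(
                tumor_radius=max(r_new, grid.h), extent=grid.extent, h=grid.h,
                params=grid.params, tumor_center=grid.tumor_center,
            )
            if sv_map is not None:
                grid.sv = sv_map

    return TreatmentHistory(cycles=records, growth=gp, schedule=schedule)
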