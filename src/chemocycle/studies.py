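"""Pre-packaged comparative studies over regimens, drug parameters and doses.

Each study re-runs the full cycle pipeline (synthetic vasculature, coupled
flow, delivery phase, kill, regrowth, shrinkage) per condition and seed and
returns a tidy DataFrame of endpoint summaries.  Geometry is stochastic, so
studies are usually run over several seeds and compared on seed means.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .config import RunConfig
from .growth import build_regimen
from .protocol import run_protocol

__all__ = [
    "run_condition",
    "regimen_comparison",
    "drug_parameter_sweep",
    "dose_fractionation_study",
]

_DRUG_KEYS = {
    "diffusivity": "d_diff_m2_s",
    "binding": "k_on_m3_mol_s",
    "half_life": "half_life_min",
}


def run_condition(cfg: RunConfig, seed: int | None = None):
    """Run one configured protocol end to end and return its history."""
    if seed is not None:
        cfg = cfg.model_copy(deep=True)
        cfg.seed = seed
    network = cfg.build_network()
    grid = cfg.build_grid()
    return run_protocol(
        network, grid, cfg.drug_params(), cfg.build_schedule(),
        cfg.growth_params(), delivery_hours=cfg.solver.delivery_hours,
        rtol=cfg.solver.transport_rtol,
        mu_plasma=cfg.vasculature.mu_plasma_pa_s,
    )


def _summarize(history, **labels) -> dict:
    out = dict(labels)
    out.update(
        survival_pct=history.survival_pct,
        side_effect_pct=history.side_effect_pct,
        n_cycles=len(history.cycles),
        total_dose=history.schedule.total_dose(),
        first_fkc=history.cycles[0].fkc_tumor if history.cycles else 0.0,
    )
    return out


def regimen_comparison(base: RunConfig, seeds: Sequence[int],
                       kinds: Iterable[str] = ("MTD", "LDC", "CS"),
                       horizon_months: float = 2.5) -> pd.DataFrame:
    """Compare named regimens (endpoint survival and side effects) per seed."""
    rows = []
    for kind in kinds:
        for seed in seeds:
            cfg = base.model_copy(deep=True)
            cfg.schedule.kind = kind
            cfg.schedule.horizon_months = horizon_months
            rows.append(_summarize(run_condition(cfg, seed), regimen=kind, seed=seed))
    return pd.DataFrame(rows)


def drug_parameter_sweep(base: RunConfig, param: str, values: Sequence[float],
                         seeds: Sequence[int],
                         horizon_months: float = 1.5) -> pd.DataFrame:
    """Sweep one drug property over an MTD-style schedule.

    ``param`` is one of 'diffusivity' (m^2/s), 'binding' (m^3/(mol·s)) or
    'half_life' (minutes).
    """
    key = _DRUG_KEYS[param]
    rows = []
    for value in values:
        for seed in seeds:
            cfg = base.model_copy(deep=True)
            cfg.schedule.kind = "MTD"
            cfg.schedule.horizon_months = horizon_months
            setattr(cfg.drug, key, value)
            rows.append(_summarize(run_condition(cfg, seed), param=param,
                                   value=value, seed=seed))
    return pd.DataFrame(rows)


def dose_fractionation_study(base: RunConfig, seeds: Sequence[int],
                             plans: Sequence[tuple[float, float]] = (
                                 (0.5, 0.25), (1.0, 0.5), (1.5, 0.75)),
                             horizon_months: float = 1.4999) -> pd.DataFrame:
    """Equal cumulative dose delivered as different per-injection sizes.

    Each plan is (dose fraction of C_p, interval in months); with the
    default horizon every plan delivers the same total dose.
    """
    rows = []
    for dose, interval in plans:
        for seed in seeds:
            cfg = base.model_copy(deep=True)
            cfg.schedule.kind = "MTD"
            cfg.schedule.mtd_dose = dose
            cfg.schedule.mtd_interval_months = interval
            cfg.schedule.horizon_months = horizon_months
            rows.append(_summarize(run_condition(cfg, seed), dose=dose,
                                   interval=interval, seed=seed))
    return pd.DataFrame(rows)
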